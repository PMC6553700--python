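"""Pipeline orchestration and table/JSON reporting.

``run_discover`` drives the full per-family workflow — load annotated
variants, apply the rarity filter, find variants shared by the sequenced
affected members, infer genotypes and evaluate co-segregation — and writes
a candidate table, a JSON result set and a filter-attrition log in which
every excluded variant carries a machine-readable reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .association import (
    AssociationResult,
    CarrierCounts,
    format_or_ci,
    format_percent,
    odds_ratio,
)
from .exceptions import FamsegError, InsufficientDataError
from .pedigree import Pedigree, parse_ped
from .segregation import SEGREGATING, evaluate_segregation, nominate_candidates
from .variant_filter import (
    FilterCriteria,
    apply_filter,
    attach_frequencies,
    load_frequency_table,
    load_variants,
    shared_by_affected,
)

log = logging.getLogger("famseg")


@dataclass
class RunConfig:
    ped_path: Path
    vcf_paths: dict[str, Path]  # family_id -> per-family VCF
    freq_paths: list[Path] = field(default_factory=list)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    affected_fraction_threshold: float = 0.75
    max_unaffected_carriers: int = 1
    consequence_tag: str = "GENECONS"
    outdir: Path = Path("famseg_out")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.affected_fraction_threshold <= 1:
            raise FamsegError("affected_fraction_threshold must be in (0, 1]")
        if self.max_unaffected_carriers < 0:
            raise FamsegError("max_unaffected_carriers must be >= 0")
        missing = [
            str(p)
            for p in [self.ped_path, *self.vcf_paths.values(), *self.freq_paths]
            if not Path(p).exists()
        ]
        if missing:
            raise FamsegError(f"input file(s) not found: {missing}")


_TABLE_COLUMNS = [
    "family_id",
    "gene",
    "variant_key",
    "consequence",
    "mode",
    "n_affected_carriers",
    "n_affected_informative",
    "affected_fraction",
    "n_unaffected_carriers_counted",
    "obligate_carriers",
    "cadd_phred",
    "db_frequencies",
    "verdict",
]


def run_discover(cfg: RunConfig) -> dict:
    """Run discovery for every family and write report files.

    Returns a summary dict: per-family nominations, attrition counts per
    stage (loaded → rare → shared → segregating) and output paths.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peds = {p.family_id: p for p in parse_ped(cfg.ped_path)}
    tables = [load_frequency_table(p) for p in cfg.freq_paths]

    rows: list[dict] = []
    summary: dict = {"families": {}, "outputs": {}}
    for fid, vcf_path in cfg.vcf_paths.items():
        if fid not in peds:
            raise FamsegError(f"family {fid!r} has a VCF but no pedigree")
        ped = peds[fid]
        loaded = load_variants(vcf_path, cfg.consequence_tag)
        loaded = attach_frequencies(loaded, tables)
        rare = apply_filter(loaded, cfg.criteria)
        attrition = {"loaded": len(loaded), "rare": len(rare)}
        try:
            shared = shared_by_affected(rare, ped)
        except InsufficientDataError as exc:
            log.warning("family %s skipped: %s", fid, exc)
            summary["families"][fid] = {
                "status": "insufficient_data",
                "attrition": attrition,
                "nominations": [],
            }
            continue
        attrition["shared"] = len(shared.records)
        attrition["share_mode"] = shared.mode
        nominated = nominate_candidates(ped, shared)
        attrition["segregating"] = len(nominated)
        by_key = {r.variant_key: r for r in shared.records}
        fam_rows = []
        for res in nominated:
            rec = by_key[res.variant_key]
            fam_rows.append(
                {
                    "family_id": fid,
                    "gene": rec.gene,
                    "variant_key": res.variant_key,
                    "consequence": rec.consequence,
                    "mode": res.mode,
                    "n_affected_carriers": res.n_affected_carriers,
                    "n_affected_informative": res.n_affected_informative,
                    "affected_fraction": round(res.affected_fraction, 4),
                    "n_unaffected_carriers_counted": res.n_unaffected_carriers_counted,
                    "obligate_carriers": ",".join(sorted(res.obligate_carriers)),
                    "cadd_phred": rec.cadd_phred,
                    "db_frequencies": ";".join(
                        f"{db}={format_percent(f)}"
                        for db, f in sorted(rec.db_frequencies.items())
                    ),
                    "verdict": res.verdict,
                }
            )
        if not fam_rows:  # explicit unresolved row
            fam_rows.append(
                {c: "" for c in _TABLE_COLUMNS}
                | {"family_id": fid, "verdict": "unresolved"}
            )
        rows.extend(fam_rows)
        summary["families"][fid] = {
            "status": "resolved" if nominated else "unresolved",
            "attrition": attrition,
            "nominations": [r["variant_key"] for r in fam_rows if r["verdict"] == SEGREGATING],
        }

    table_path = outdir / "candidates.tsv"
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(table_path, sep="\t", index=False)
    json_path = outdir / "discover.json"
    with json_path.open("w") as fh:
        json.dump(summary["families"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["outputs"] = {"table": str(table_path), "json": str(json_path)}
    for fid, info in summary["families"].items():
        log.info("family %s: %s %s", fid, info["status"], info["attrition"])
    return summary


def run_assoc(counts_path: Path, out_path: Path | None = None) -> pd.DataFrame:
    """Compute MAFs and odds ratios for a TSV of carrier counts with columns:
    label, cases_carriers, cases_n, controls_carriers, controls_n."""
    df = pd.read_csv(counts_path, sep="\t")
    rows = []
    errors = []
    for i, row in df.iterrows():
        try:
            counts = CarrierCounts(
                int(row.cases_carriers),
                int(row.cases_n),
                int(row.controls_carriers),
                int(row.controls_n),
            )
            res = odds_ratio(counts)
        except (FamsegError, ValueError, TypeError) as exc:
            errors.append(f"row {i} ({row.get('label', '?')}): {exc}")
            continue
        rows.append(
            {
                "label": row.get("label", f"row{i}"),
                "maf_cases": format_percent(res.maf_cases),
                "maf_controls": format_percent(res.maf_controls),
                "or_ci95": format_or_ci(res),
                "correction_applied": res.correction_applied,
            }
        )
    if errors:
        raise FamsegError("malformed count rows:\n" + "\n".join(errors))
    out = pd.DataFrame(
        rows,
        columns=["label", "maf_cases", "maf_controls", "or_ci95", "correction_applied"],
    )
    if out_path is not None:
        out.to_csv(out_path, sep="\t", index=False)
    return out
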