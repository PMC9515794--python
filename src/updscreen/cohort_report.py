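"""Per-trio screening driver and cohort-level aggregation.

``screen_trio`` composes the whole pipeline for one proband: chromosome
metrics → whole-chromosome classification → segmental window scan (on
chromosomes without a whole-chromosome call) → coverage-based resolution.
``screen_cohort`` aggregates per-chromosome metric distributions across
probands, flags boxplot outliers, tallies events and renders the cohort
prevalence.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .genotype_store import TrioGenotypes, genome_mean_coverage, ROLES
from .upd_core import (
    CandidateRegion,
    ChromosomeCall,
    WHOLE_CHROMOSOME_CALLS,
    CALL_UPID,
    CALL_UPHD,
    chromosome_stats,
    classify_chromosome,
    merge_windows,
    resolve_region,
    scan_partial,
)

logger = logging.getLogger("updscreen")


@dataclass
class TrioReport:
    """Full screen result for one proband."""

    proband_id: str
    sex: str
    calls: list  # ChromosomeCall, one per screened chromosome
    regions: list  # CandidateRegion
    genome_mean_depth: dict  # role -> reads
    filter_accounting: dict = field(default_factory=dict)

    def whole_chromosome_events(self) -> list:
        return [c for c in self.calls if c.call in WHOLE_CHROMOSOME_CALLS]

    def to_dict(self) -> dict:
        return {
            "proband_id": self.proband_id,
            "sex": self.sex,
            "calls": [c.to_dict() for c in self.calls],
            "regions": [r.to_dict() for r in self.regions],
            "genome_mean_depth": self.genome_mean_depth,
            "filter_accounting": self.filter_accounting,
        }


def screen_trio(
    trio: TrioGenotypes,
    config: RunConfig | None = None,
    proband_id: str = "PROBAND",
    genome_mean_depth: dict | None = None,
    filter_accounting: dict | None = None,
) -> TrioReport:
    """Run the full screen on one loaded, filtered trio.

    ``genome_mean_depth`` (role → mean reads) should be computed on the
    pre-filter trio; when omitted it falls back to the depths still present
    in ``trio``.  A chromosome with a whole-chromosome disomy call is not
    scanned segmentally (the segmental signal is subsumed; the suppression
    is logged).
    """
    if config is None:
        config = RunConfig()
    if genome_mean_depth is None:
        genome_mean_depth = {r: genome_mean_coverage(trio, r) for r in ROLES}

    calls: list = []
    regions: list = []
    w = config.windows
    for chrom in trio.screened_chromosomes():
        stats = chromosome_stats(trio, chrom)
        call = classify_chromosome(stats, config.thresholds, trio.proband_sex)
        calls.append(call)
        if call.call in WHOLE_CHROMOSOME_CALLS:
            logger.info(
                "%s chr%s: whole-chromosome %s (%s); segmental scan suppressed",
                proband_id, chrom, call.call, call.parent,
            )
            continue
        windows = scan_partial(
            trio, chrom,
            window_size=w.window_size,
            min_errors=w.min_errors,
            het_max_pct=w.het_max_pct,
        )
        if not windows:
            continue
        for interval in merge_windows(windows):
            regions.append(resolve_region(
                trio, chrom, interval,
                genome_mean_depth["proband"],
                ratio_min=w.ratio_min,
            ))
    logger.info(
        "%s: %d whole-chromosome events, %d candidate regions",
        proband_id, sum(c.call in WHOLE_CHROMOSOME_CALLS for c in calls), len(regions),
    )
    return TrioReport(
        proband_id=proband_id,
        sex=trio.proband_sex,
        calls=calls,
        regions=regions,
        genome_mean_depth={k: float(v) for k, v in genome_mean_depth.items()},
        filter_accounting=filter_accounting or {},
    )


def prevalence(n_trios: int, n_events: int) -> str:
    """Render cohort prevalence as '1 in N', N = n_trios / n_events rounded
    to the nearest integer (half away from zero)."""
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events == 0:
        return f"0 events in {n_trios}"
    return f"1 in {int(n_trios / n_events + 0.5)}"


@dataclass
class CohortSummary:
    """Cohort-level distributions, outliers, tallies and prevalence."""

    n_trios: int
    # chromosome -> {"pct_ab": five-number dict, "pct_het": five-number dict}
    distributions: dict
    # list of {"proband", "chromosome", "metric", "value"}
    outliers: list
    # (call, parent) tally over all whole-chromosome events
    event_tally: dict
    prevalence: dict  # {"upid": text, "upd": text}

    def outlier_pairs(self, metric: str) -> set:
        return {(o["proband"], o["chromosome"]) for o in self.outliers if o["metric"] == metric}

    def to_dict(self) -> dict:
        return {
            "n_trios": self.n_trios,
            "distributions": self.distributions,
            "outliers": self.outliers,
            "event_tally": {f"{c}:{p}": n for (c, p), n in self.event_tally.items()},
            "prevalence": self.prevalence,
        }


def _five_number(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(values.max()), "n": int(values.size),
    }


def screen_cohort(reports: list, config: RunConfig | None = None) -> CohortSummary:
    """Aggregate trio reports into the cohort summary.

    Outliers use a Tukey-style fence widened to a minimum span (see
    :class:`updscreen.config.OutlierConfig`): pct_ab is flagged on the low
    tail only (uniparental skew depresses AB), heterozygosity on both tails
    (isodisomy low, trisomy high).
    """
    if not reports:
        raise ValueError("need at least one trio report")
    if config is None:
        config = RunConfig()
    oc = config.outliers

    rows = []
    for rep in reports:
        for call in rep.calls:
            s = call.stats
            rows.append((rep.proband_id, s.chromosome, s.pct_ab, s.pct_het))
    table = pd.DataFrame(rows, columns=["proband", "chromosome", "pct_ab", "pct_het"])

    distributions: dict = {}
    outliers: list = []
    for chrom, grp in table.groupby("chromosome", sort=False):
        distributions[chrom] = {}
        for metric, tails in (("pct_ab", "low"), ("pct_het", "both")):
            vals = grp[metric].to_numpy(float)
            ok = ~np.isnan(vals)
            if not ok.any():
                continue
            v = vals[ok]
            summ = _five_number(v)
            distributions[chrom][metric] = summ
            fence = max(oc.iqr_mult * (summ["q3"] - summ["q1"]), oc.min_fence)
            lo, hi = summ["q1"] - fence, summ["q3"] + fence
            for proband, value in zip(grp["proband"].to_numpy()[ok], v):
                if value < lo or (tails == "both" and value > hi):
                    outliers.append({
                        "proband": str(proband), "chromosome": chrom,
                        "metric": metric, "value": float(value),
                    })

    tally: dict = {}
    for rep in reports:
        for call in rep.calls:
            key = (call.call, call.parent)
            tally[key] = tally.get(key, 0) + 1

    n = len(reports)
    n_upid_probands = sum(
        any(c.call == CALL_UPID for c in rep.calls) for rep in reports
    )
    n_upd_probands = sum(
        any(c.call in (CALL_UPID, CALL_UPHD) for c in rep.calls) for rep in reports
    )
    return CohortSummary(
        n_trios=n,
        distributions=distributions,
        outliers=outliers,
        event_tally=tally,
        prevalence={
            "upid": prevalence(n, n_upid_probands),
            "upd": prevalence(n, n_upd_probands),
        },
    )


# ---------------------------------------------------------------------------
# export

def _provenance(config: RunConfig | None) -> str:
    cfg = (config or RunConfig()).to_dict()
    return f"updscreen v{__version__} config={json.dumps(cfg, sort_keys=True)}"


_TSV_COLUMNS = [
    "proband", "chromosome", "n_nonmissing", "n_het", "pct_het",
    "n_informative", "n_ab", "pct_ab", "pct_match_mother", "pct_match_father",
    "call", "parent",
]


def _calls_rows(proband_id: str, calls: list) -> list:
    rows = []
    for c in calls:
        s = c.stats
        rows.append([
            proband_id, s.chromosome, s.n_nonmissing, s.n_het,
            round(s.pct_het, 4) if s.n_nonmissing else "NA",
            s.n_informative, s.n_ab,
            round(s.pct_ab, 4) if s.n_informative else "NA",
            round(s.pct_match_mother, 4) if s.n_informative else "NA",
            round(s.pct_match_father, 4) if s.n_informative else "NA",
            c.call, c.parent,
        ])
    return rows


def _write_tsv(path: str, header: list, rows: list, provenance: str) -> None:
    with open(path, "w") as out:
        out.write(f"# {provenance}\n")
        out.write("\t".join(header) + "\n")
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")


def _write_regions_bed(path: str, regions: list, provenance: str, probands: list | None = None) -> None:
    with open(path, "w") as out:
        out.write(f"# {provenance}\n")
        for i, r in enumerate(regions):
            name = f"{r.resolution}:{r.parent}"
            if probands:
                name = f"{probands[i]}:{name}"
            out.write(
                f"chr{r.chromosome}\t{r.start - 1}\t{r.end - 1}\t{name}\t{r.n_mendelian_errors}\t.\n"
            )


def export(report, out_dir: str, config: RunConfig | None = None) -> dict:
    """Write a :class:`TrioReport` or :class:`CohortSummary` to ``out_dir``.

    Emits a per-chromosome TSV, a JSON full report, and a BED of candidate
    regions (TrioReport only); every file carries a provenance header.
    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    prov = _provenance(config)
    paths: dict = {}
    if isinstance(report, TrioReport):
        tsv = os.path.join(out_dir, f"{report.proband_id}.chromosomes.tsv")
        _write_tsv(tsv, _TSV_COLUMNS, _calls_rows(report.proband_id, report.calls), prov)
        paths["tsv"] = tsv
        bed = os.path.join(out_dir, f"{report.proband_id}.regions.bed")
        _write_regions_bed(bed, report.regions, prov)
        paths["bed"] = bed
        js = os.path.join(out_dir, f"{report.proband_id}.report.json")
        with open(js, "w") as fh:
            json.dump({"provenance": prov, **report.to_dict()}, fh, indent=1, sort_keys=True)
        paths["json"] = js
    elif isinstance(report, CohortSummary):
        js = os.path.join(out_dir, "cohort.summary.json")
        with open(js, "w") as fh:
            json.dump({"provenance": prov, **report.to_dict()}, fh, indent=1, sort_keys=True)
        paths["json"] = js
    else:
        raise TypeError(f"cannot export object of type {type(report).__name__}")
    return paths


def export_cohort_tables(reports: list, summary: CohortSummary, out_dir: str,
                         config: RunConfig | None = None) -> dict:
    """Write the cohort-wide per-chromosome TSV (one row per proband per
    screened chromosome — sufficient to redraw the AB%/heterozygosity
    boxplots), the merged regions BED and the summary JSON."""
    os.makedirs(out_dir, exist_ok=True)
    prov = _provenance(config)
    rows: list = []
    regions: list = []
    region_probands: list = []
    for rep in reports:
        rows.extend(_calls_rows(rep.proband_id, rep.calls))
        regions.extend(rep.regions)
        region_probands.extend([rep.proband_id] * len(rep.regions))
    tsv = os.path.join(out_dir, "cohort.chromosomes.tsv")
    _write_tsv(tsv, _TSV_COLUMNS, rows, prov)
    bed = os.path.join(out_dir, "cohort.regions.bed")
    _write_regions_bed(bed, regions, prov, region_probands)
    paths = export(summary, out_dir, config)
    paths.update({"tsv": tsv, "bed": bed})
    return paths
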