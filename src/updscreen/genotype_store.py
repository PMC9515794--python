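"""Trio genotype I/O and site/genotype filtering.

Genotypes for mother, father and proband are held in one
:class:`pandas.DataFrame` (one row per biallelic SNV site), encoded as

====  ==================
code  diploid genotype
====  ==================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing / filtered
====  ==================

The screen consumes a joint-genotyped multi-sample VCF plus a PED pedigree
that names the trio and the proband's sex.  Genotype-level filter failures
(depth, genotype quality) mark the individual call missing rather than
dropping the site, so a site can stay informative for the parents while the
proband contributes nothing; population-frequency failures remove the site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

ROLES = ("mother", "father", "proband")

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROM_ORDER = AUTOSOMES + ("X",)
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

_NUCS = frozenset("ACGT")

#: cyvcf2 ``gt_types`` codes → internal codes (cyvcf2: 0=HOM_REF, 1=HET,
#: 2=UNKNOWN, 3=HOM_ALT)
_CYVCF2_GT = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome labels: 'chr1' and '1' both become '1'."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return "X" if c in ("x", "X") else c


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_RANK.get(normalize_chrom(chrom), len(_CHROM_RANK))


class PedigreeError(ValueError):
    """The pedigree does not describe exactly one complete trio."""


@dataclass(frozen=True)
class FilterConfig:
    """Site and genotype filters applied before the screen.

    Defaults are the screen's shipped values: common biallelic SNVs
    (minor allele frequency >= 0.4), per-sample depth within [15, 100]
    and genotype quality >= 15.
    """

    maf_min: float = 0.4
    depth_min: int = 15
    depth_max: int = 100
    gq_min: int = 15
    snv_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")


@dataclass
class FilterAccounting:
    """Per-criterion accounting of what filtering removed or masked."""

    n_sites_in: int = 0
    n_sites_removed_maf: int = 0
    n_sites_out: int = 0
    # role -> {"depth_low": n, "depth_high": n, "gq_low": n}
    genotypes_masked: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites_in": int(self.n_sites_in),
            "n_sites_removed_maf": int(self.n_sites_removed_maf),
            "n_sites_out": int(self.n_sites_out),
            "genotypes_masked": {
                r: {k: int(v) for k, v in d.items()}
                for r, d in self.genotypes_masked.items()
            },
        }


@dataclass(frozen=True)
class Pedigree:
    """One resolved trio: sample names per role plus proband sex."""

    mother: str
    father: str
    proband: str
    proband_sex: str  # "male" | "female"

    @property
    def samples(self) -> dict:
        return {"mother": self.mother, "father": self.father, "proband": self.proband}


@dataclass
class TrioGenotypes:
    """Filtered or unfiltered per-site trio genotype table.

    ``df`` columns: chrom (normalized, no 'chr' prefix), pos (1-based), ref,
    alt, af (alternate-allele population frequency), gt_/dp_/gq_ per role.
    Rows sorted by (chromosome rank, position).
    """

    df: pd.DataFrame
    samples: dict
    proband_sex: str

    def __post_init__(self) -> None:
        if self.proband_sex not in ("male", "female"):
            raise ValueError(f"proband_sex must be male/female, got {self.proband_sex}")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list:
        seen = self.df["chrom"].unique().tolist()
        return sorted(seen, key=chrom_sort_key)

    def subset(self, chromosome: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == normalize_chrom(chromosome)]

    def screened_chromosomes(self) -> tuple:
        """Chromosome set the screen covers: autosomes, plus X for females."""
        return CHROM_ORDER if self.proband_sex == "female" else AUTOSOMES


REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "af") + tuple(
    f"{p}_{r}" for p in ("gt", "dp", "gq") for r in ROLES
)


def trio_from_frame(df: pd.DataFrame, proband_sex: str, samples: dict | None = None) -> TrioGenotypes:
    """Wrap a raw genotype table (e.g. from the simulator) as TrioGenotypes."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    out = df.copy()
    out["chrom"] = out["chrom"].map(normalize_chrom)
    out["_rank"] = out["chrom"].map(chrom_sort_key)
    out = out.sort_values(["_rank", "pos"], kind="stable").drop(columns="_rank")
    out = out.reset_index(drop=True)
    if samples is None:
        samples = {r: r.upper() for r in ROLES}
    return TrioGenotypes(df=out, samples=dict(samples), proband_sex=proband_sex)


def parse_pedigree(ped_path: str) -> Pedigree:
    """Parse a 6-column PED file and resolve exactly one mother/father/proband trio.

    The proband is the individual whose father and mother columns are both
    non-zero; its sex column (1=male, 2=female) must be set.
    """
    rows = []
    with open(ped_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"PED line has <6 columns: {line!r}")
            rows.append(parts[:6])
    probands = [r for r in rows if r[2] not in ("0", ".") and r[3] not in ("0", ".")]
    if len(probands) != 1:
        raise PedigreeError(
            f"pedigree must declare exactly one proband with both parents, found {len(probands)}"
        )
    fam, child, father, mother, sex, _pheno = probands[0]
    if sex == "1":
        proband_sex = "male"
    elif sex == "2":
        proband_sex = "female"
    else:
        raise PedigreeError(f"proband sex must be 1 or 2, got {sex!r}")
    individuals = {r[1] for r in rows}
    for parent, label in ((mother, "mother"), (father, "father")):
        if parent not in individuals:
            raise PedigreeError(f"{label} {parent!r} of proband {child!r} not in pedigree")
    return Pedigree(mother=mother, father=father, proband=child, proband_sex=proband_sex)


def _load_site_list(path: str) -> dict:
    """Load an external allele-frequency site list (TSV: chrom pos ref alt af)."""
    table = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "pos", "ref", "alt", "af"], header=None,
        dtype={"pos": int, "af": float},
    )
    return {
        (normalize_chrom(c), int(p), r, a): float(f)
        for c, p, r, a, f in table.itertuples(index=False)
    }


def load_trio(vcf_path: str, pedigree, af_source: str = "AF") -> TrioGenotypes:
    """Load trio genotypes from a joint-genotyped VCF.

    Parameters
    ----------
    vcf_path
        Multi-sample VCF v4.2 (plain or bgzipped).
    pedigree
        Path to a PED file, or an already-parsed :class:`Pedigree`.
    af_source
        INFO field carrying the alternate-allele population frequency
        (default ``"AF"``), or a path to a TSV site list
        (chrom, pos, ref, alt, af).  Sites with no frequency raise an error
        when ``af_source`` is an INFO field, and are skipped for a site list
        (the list defines the screened panel).

    Only biallelic SNVs are loaded; multi-allelic and non-SNV records are
    excluded (counts of each are not tracked here — upstream callers see only
    the biallelic SNV panel, which is what the screen is defined on).
    """
    ped = pedigree if isinstance(pedigree, Pedigree) else parse_pedigree(pedigree)
    vcf = VCF(vcf_path)
    sample_idx = {}
    for role, name in ped.samples.items():
        if name not in vcf.samples:
            raise ValueError(f"sample {name!r} ({role}) named in pedigree absent from VCF")
        sample_idx[role] = vcf.samples.index(name)

    site_af = None
    if os.sep in af_source or os.path.exists(af_source):
        site_af = _load_site_list(af_source)

    records: list = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
            continue
        chrom = normalize_chrom(v.CHROM)
        if site_af is not None:
            af = site_af.get((chrom, v.POS, ref, alt))
            if af is None:
                continue
        else:
            raw = v.INFO.get(af_source)
            if raw is None:
                raise ValueError(
                    f"site {v.CHROM}:{v.POS} lacks INFO/{af_source}; "
                    "provide a site list or annotate the VCF"
                )
            af = float(raw[0] if isinstance(raw, tuple) else raw)

        gts = v.gt_types
        dps = v.format("DP")
        gqs = v.gt_quals
        row = [chrom, v.POS, ref, alt, af]
        for part in ("gt", "dp", "gq"):
            for role in ROLES:
                i = sample_idx[role]
                if part == "gt":
                    row.append(_CYVCF2_GT.get(int(gts[i]), MISSING))
                elif part == "dp":
                    d = -1 if dps is None else int(dps[i][0])
                    row.append(d if d >= 0 else -1)
                else:
                    q = float(gqs[i])
                    row.append(int(q) if q >= 0 else -1)
        records.append(row)

    df = pd.DataFrame(records, columns=list(REQUIRED_COLUMNS))
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=("int64" if c not in ("chrom", "ref", "alt", "af") else "object"))
                           for c in REQUIRED_COLUMNS})
        df["af"] = df["af"].astype(float)
    return trio_from_frame(df, proband_sex=ped.proband_sex, samples=ped.samples)


def apply_filters(trio: TrioGenotypes, config: FilterConfig | None = None):
    """Apply site- and genotype-level filters.

    Returns ``(filtered_trio, accounting)``.  Sites whose population minor
    allele frequency falls below ``maf_min`` are removed; a genotype call with
    out-of-range depth or low genotype quality becomes missing for that sample
    only.  Idempotent: re-applying the same config is a no-op.
    """
    if config is None:
        config = FilterConfig()
    df = trio.df.copy()
    acc = FilterAccounting(n_sites_in=len(df))

    maf = np.minimum(df["af"].to_numpy(float), 1.0 - df["af"].to_numpy(float))
    keep = maf >= config.maf_min
    acc.n_sites_removed_maf = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)

    for role in ROLES:
        gt = df[f"gt_{role}"].to_numpy()
        dp = df[f"dp_{role}"].to_numpy()
        gq = df[f"gq_{role}"].to_numpy()
        called = gt != MISSING
        low = called & (dp < config.depth_min)
        high = called & (dp > config.depth_max)
        badq = called & ~low & ~high & (gq < config.gq_min)
        acc.genotypes_masked[role] = {
            "depth_low": int(low.sum()),
            "depth_high": int(high.sum()),
            "gq_low": int(badq.sum()),
        }
        df.loc[low | high | badq, f"gt_{role}"] = MISSING

    acc.n_sites_out = len(df)
    out = TrioGenotypes(df=df, samples=trio.samples, proband_sex=trio.proband_sex)
    return out, acc


def genome_mean_coverage(trio: TrioGenotypes, sample_role: str) -> float:
    """Mean per-site read depth for one role across all loaded sites.

    Acts as the genome-wide coverage proxy; compute it on the *pre-filter*
    trio so masked genotypes still contribute their depth.
    """
    if sample_role not in ROLES:
        raise ValueError(f"unknown role {sample_role!r}")
    dp = trio.df[f"dp_{sample_role}"].to_numpy()
    dp = dp[dp >= 0]
    if dp.size == 0:
        raise ValueError(f"no depth data for role {sample_role!r}")
    return float(dp.mean())
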