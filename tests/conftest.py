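import numpy as np
import pytest

from updscreen import trio_sim as ts
from updscreen.genotype_store import trio_from_frame


def make_trio(
    events=None,
    seed=0,
    sex="female",
    n_sites=500,
    chroms=("1", "2", "3"),
    error_rate=0.0,
    mean_depth=40.0,
    gq_fail_rate=0.0,
    af_low=0.4,
    af_high=0.6,
):
    """Simulate one trio on a small panel and wrap it as TrioGenotypes."""
    lengths = {c: ts.default_chrom_lengths()[c] for c in chroms}
    panel = ts.simulate_site_panel(n_sites, lengths, af_low, af_high, seed=seed)
    scenario = ts.SimScenario(
        seed=seed + 1,
        events=events or {},
        genotype_error_rate=error_rate,
        mean_depth=mean_depth,
        gq_fail_rate=gq_fail_rate,
    )
    table, truth = ts.simulate_trio(panel, scenario, sex, lengths)
    return trio_from_frame(table, sex), table, truth


def random_trio_frame(rng, n_sites, chrom="1", length=20_000_000):
    """Random (Mendelian-inconsistent) genotype table for scan stress tests."""
    import pandas as pd

    pos = np.sort(rng.choice(length, n_sites, replace=False)) + 1
    frame = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
             "af": rng.uniform(0.4, 0.6, n_sites)}
    for role in ("mother", "father", "proband"):
        frame[f"gt_{role}"] = rng.choice([-1, 0, 1, 2], n_sites, p=[0.02, 0.32, 0.34, 0.32])
        frame[f"dp_{role}"] = rng.integers(20, 60, n_sites)
        frame[f"gq_{role}"] = 99
    return pd.DataFrame(frame)


# --- independent transmission-enumeration oracle -------------------------

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def oracle_consistent(gm, gf, gp):
    """Brute force over all parental allele transmissions."""
    want = tuple(sorted(_ALLELES[gp]))
    return any(
        tuple(sorted((a, b))) == want
        for a in _ALLELES[gm]
        for b in _ALLELES[gf]
    )


def oracle_site(gm, gf, gp):
    """Independent per-site classification; returns (informative, merror, match)."""
    merror = gm >= 0 and gf >= 0 and gp >= 0 and not oracle_consistent(gm, gf, gp)
    informative = (gm, gf) in ((0, 2), (2, 0))
    match = "not_applicable"
    if informative and gp >= 0:
        if gp == 1:
            match = "biparental_het"
        elif gp == gm:
            match = "mother"
        else:
            match = "father"
    return informative, merror, match


def oracle_scan(df, window_size, min_errors, het_max_pct):
    """Exhaustive error-anchored window evaluation (no cumsum tricks)."""
    pos = df["pos"].to_numpy()
    cls = [oracle_site(m, f, p) for m, f, p in
           zip(df["gt_mother"], df["gt_father"], df["gt_proband"])]
    informative = np.array([c[0] for c in cls])
    merror = np.array([c[1] for c in cls])
    het_inf = np.array([c[2] == "biparental_het" for c in cls])
    inf_called = informative & (df["gt_proband"].to_numpy() >= 0)
    out = []
    for i in np.flatnonzero(merror):
        sel = (pos >= pos[i]) & (pos < pos[i] + window_size)
        n_err = int(merror[sel].sum())
        if n_err < min_errors:
            continue
        n_inf = int(inf_called[sel].sum())
        n_het = int(het_inf[sel].sum())
        if n_inf and 100.0 * n_het / n_inf > het_max_pct:
            continue
        out.append((int(pos[i]), int(pos[i]) + window_size, n_err))
    return out
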