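"""Summary statistics for sequence and dominant-marker data.

The statistic set mirrors what the ABC machinery consumes, computed with
one code path for observed and simulated datasets:

* per sequence locus and group: Tajima's D and nucleotide diversity pi
  (mean pairwise Kimura 2-parameter distance);
* per sequence locus and group pair: Phi_ST from an AMOVA decomposition
  of squared K2P distances;
* for the AFLP matrix: expected heterozygosity per group, and per group
  pair the mean and standard deviation of per-locus F_ST plus the mean
  Jaccard distance between individuals' band profiles.

With the study design of 4 sequence loci and 4 groups (2 localities x 2
ecotypes) this yields 56 sequence statistics, 22 AFLP statistics and 78
combined.  Bases are encoded A=0, C=1, G=2, T=3, so a substitution is a
transition exactly when ``a ^ b == 2``.  Undefined statistics are
returned as NaN sentinels and filtered downstream.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .coalescent_sim import MultiMarkerDataset

__all__ = [
    "k2p_distance",
    "k2p_pairwise",
    "pi_k2p",
    "tajimas_d",
    "phi_st",
    "aflp_allele_freqs",
    "aflp_heterozygosity",
    "aflp_fst_pair",
    "jaccard_distance",
    "assemble_vector",
]


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def k2p_distance(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Kimura 2-parameter distance in substitutions/site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the observed
    transition and transversion fractions.  Saturated pairs (either log
    argument <= 0) return NaN and are excluded by callers.
    """
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    x = a ^ b
    L = a.shape[-1]
    P = np.count_nonzero(x == 2) / L
    Q = np.count_nonzero((x != 0) & (x != 2)) / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_pairwise(alignment: np.ndarray) -> np.ndarray:
    """All pairwise K2P distances of an (n, L) alignment (NaN where
    saturated).  Only segregating columns are scanned."""
    aln = np.asarray(alignment)
    n, L = aln.shape
    seg = (aln != aln[0]).any(axis=0)
    sub = aln[:, seg]
    x = sub[:, None, :] ^ sub[None, :, :]
    P = np.count_nonzero(x == 2, axis=2) / L
    Q = np.count_nonzero((x != 0) & (x != 2), axis=2) / L
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0),
                     -0.5 * np.log(np.maximum(w1, 1e-300))
                     - 0.25 * np.log(np.maximum(w2, 1e-300)),
                     np.nan)
    return d


def pi_k2p(alignment: np.ndarray) -> float:
    """Mean pairwise K2P distance over all unordered pairs (NaN pairs
    excluded; NaN sentinel if fewer than 2 sequences)."""
    aln = np.asarray(alignment)
    if aln.shape[0] < 2:
        return math.nan
    d = k2p_pairwise(aln)
    iu = np.triu_indices(aln.shape[0], k=1)
    return float(np.nanmean(d[iu]))


def tajimas_d(alignment: np.ndarray) -> float:
    """Tajima's D from raw pairwise difference counts and segregating
    sites, with the standard variance coefficients; 0 when S = 0."""
    aln = np.asarray(alignment)
    n = aln.shape[0]
    if n < 2:
        return math.nan
    seg = (aln != aln[0]).any(axis=0)
    S = int(seg.sum())
    if S == 0:
        return 0.0
    sub = aln[:, seg]
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    pi_raw = float(diff[iu].mean())
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (pi_raw - S / a1) / math.sqrt(var)


def _ssd(d2: np.ndarray, idx_groups: list[np.ndarray]) -> tuple[float, float]:
    """Within- and total sums of squared deviations of a two-level AMOVA
    on a squared-distance matrix.  NaN (saturated) entries are replaced by
    the mean finite squared distance of the relevant pair set."""
    n_tot = sum(len(ix) for ix in idx_groups)
    all_ix = np.concatenate(idx_groups)
    iu = np.triu_indices(n_tot, k=1)
    sub = d2[np.ix_(all_ix, all_ix)]
    pair_vals = sub[iu]
    tot_mean = np.nanmean(pair_vals) if np.isfinite(pair_vals).any() else 0.0
    ss_total = float(np.where(np.isnan(pair_vals), tot_mean, pair_vals).sum()) / n_tot
    ss_within = 0.0
    for ix in idx_groups:
        g = d2[np.ix_(ix, ix)]
        gu = np.triu_indices(len(ix), k=1)
        vals = g[gu]
        if vals.size:
            m = np.nanmean(vals) if np.isfinite(vals).any() else 0.0
            ss_within += float(np.where(np.isnan(vals), m, vals).sum()) / len(ix)
    return ss_within, ss_total


def _phi_from_d2(d2: np.ndarray, na: int, nb: int) -> float:
    N, G = na + nb, 2
    groups = [np.arange(na), np.arange(na, N)]
    ss_within, ss_total = _ssd(d2, groups)
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (N - G)
    n_c = (N - (na**2 + nb**2) / N) / (G - 1)
    sigma_a = (ss_among / (G - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-group AMOVA fixation index on squared K2P distances.

    Phi_ST = sigma2_among / (sigma2_among + sigma2_within); negative
    estimates are retained as computed.  NaN sentinel when either group
    has fewer than 2 sequences.
    """
    na, nb = group_a.shape[0], group_b.shape[0]
    if na < 2 or nb < 2:
        return math.nan
    aln = np.concatenate([group_a, group_b], axis=0)
    d2 = k2p_pairwise(aln) ** 2
    return _phi_from_d2(d2, na, nb)


def _tajimas_d_from_counts(diff: np.ndarray, S: int, n: int) -> float:
    if n < 2:
        return math.nan
    if S == 0:
        return 0.0
    iu = np.triu_indices(n, k=1)
    pi_raw = float(diff[iu].mean())
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (pi_raw - S / a1) / math.sqrt(var)


def _seq_locus_block(by_group: dict[str, np.ndarray], groups, pairs):
    """Per-locus statistics from one shared pairwise comparison pass:
    (D, pi) per group and Phi_ST per pair."""
    alns = [by_group[g] for g in groups]
    ns = [a.shape[0] for a in alns]
    ofs = np.concatenate([[0], np.cumsum(ns)])
    aln = np.concatenate(alns, axis=0)
    L = aln.shape[1]
    seg = (aln != aln[0]).any(axis=0)
    sub = aln[:, seg]
    x = sub[:, None, :] ^ sub[None, :, :]
    nz = x != 0
    ts = x == 2
    diff = nz.sum(axis=2)
    P = ts.sum(axis=2) / L
    Q = (diff / L) - P
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0),
                     -0.5 * np.log(np.maximum(w1, 1e-300))
                     - 0.25 * np.log(np.maximum(w2, 1e-300)),
                     np.nan)
    d2 = d**2
    per_group, per_pair = {}, {}
    for gi, g in enumerate(groups):
        sl = slice(ofs[gi], ofs[gi + 1])
        n = ns[gi]
        gsub = sub[sl]
        S = int((gsub != gsub[0]).any(axis=0).sum()) if n else 0
        dloc = d[sl, sl]
        iu = np.triu_indices(n, k=1)
        pi = float(np.nanmean(dloc[iu])) if n >= 2 else math.nan
        per_group[g] = (_tajimas_d_from_counts(diff[sl, sl], S, n), pi)
    for ga, gb in pairs:
        ia, ib = groups.index(ga), groups.index(gb)
        ix = np.concatenate([np.arange(ofs[ia], ofs[ia + 1]),
                             np.arange(ofs[ib], ofs[ib + 1])])
        per_pair[(ga, gb)] = _phi_from_d2(d2[np.ix_(ix, ix)], ns[ia], ns[ib])
    return per_group, per_pair


# ---------------------------------------------------------------------------
# AFLP statistics
# ---------------------------------------------------------------------------

def aflp_allele_freqs(matrix: np.ndarray) -> np.ndarray:
    """Per-locus absence-allele frequency q from dominant phenotypes.

    Under Hardy-Weinberg the band-absent fraction f0 estimates q^2, so
    q = sqrt(f0) (the square-root method); f0 = 0 maps to q = 0.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("need a (individuals x loci) phenotype matrix")
    f0 = 1.0 - m.mean(axis=0)
    return np.sqrt(np.clip(f0, 0.0, 1.0))


def aflp_heterozygosity(matrix: np.ndarray) -> float:
    """Expected heterozygosity 2*p*q averaged over loci."""
    q = aflp_allele_freqs(matrix)
    p = 1.0 - q
    return float(np.mean(2.0 * p * q))


def _freq_sampling_var(q: np.ndarray, n: int) -> np.ndarray:
    # delta-method variance of the square-root estimator; zero at the
    # boundaries where no absence (or no presence) phenotype was seen
    v = (1.0 - q**2) / (4.0 * n)
    return np.where((q <= 0.0) | (q >= 1.0), 0.0, v)


def aflp_fst_pair(mat_a: np.ndarray, mat_b: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Mean and SD of per-locus F_ST between two groups of dominant
    phenotypes, plus the per-locus values.

    Per locus, F_ST = (H_T - H_S) / H_T with H_T = 2*pbar*qbar from the
    two groups' allele frequencies; the numerator (p1-p2)^2/2 is corrected
    for the sampling variance of each frequency estimate so that the
    estimator is centred on zero under panmixia.  Loci monomorphic in
    both groups (H_T = 0) are skipped; negative values are retained.
    NaN sentinels when no locus is informative.
    """
    na, nb = mat_a.shape[0], mat_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 individuals per group")
    q1 = aflp_allele_freqs(mat_a)
    q2 = aflp_allele_freqs(mat_b)
    p1, p2 = 1.0 - q1, 1.0 - q2
    v1 = _freq_sampling_var(q1, na)
    v2 = _freq_sampling_var(q2, nb)
    pbar = (p1 + p2) / 2.0
    h_t = 2.0 * pbar * (1.0 - pbar)
    informative = h_t > 0.0
    if not informative.any():
        return math.nan, math.nan, np.full(mat_a.shape[1], math.nan)
    num = ((p1 - p2) ** 2 - v1 - v2) / 2.0
    fst = np.full(mat_a.shape[1], math.nan)
    fst[informative] = num[informative] / h_t[informative]
    vals = fst[informative]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
    return float(vals.mean()), sd, fst


def jaccard_distance(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Mean Jaccard distance 1 - |shared bands| / |bands in either| over
    all between-group individual pairs (empty-union pairs skipped)."""
    a = np.asarray(mat_a, dtype=np.int64)
    b = np.asarray(mat_b, dtype=np.int64)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the locus set")
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    mask = union > 0
    if not mask.any():
        return math.nan
    return float(1.0 - (inter[mask] / union[mask]).mean())


# ---------------------------------------------------------------------------
# the ordered statistic vector
# ---------------------------------------------------------------------------

def _group_pairs(groups: tuple[str, ...]):
    return list(itertools.combinations(groups, 2))


def assemble_vector(dataset: MultiMarkerDataset, mode: str = "combined") -> pd.Series:
    """Assemble the ordered summary-statistic vector of a dataset.

    ``mode`` selects the sequence block (per locus x group: Tajima's D,
    pi; per locus x pair: Phi_ST), the AFLP block (per group: H; per
    pair: mean F_ST, SD of F_ST, Jaccard distance), or both.  For the
    4-locus, 4-group study design this gives 56, 22 and 78 statistics.
    """
    if mode not in ("sequence", "aflp", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    groups = dataset.groups
    if len(groups) != 4:
        raise ValueError("the statistic layout expects 4 groups (2 localities x 2 ecotypes)")
    pairs = _group_pairs(groups)
    names: list[str] = []
    values: list[float] = []

    if mode in ("sequence", "combined"):
        loci = list(dataset.sequences)
        blocks = {
            locus: _seq_locus_block(dataset.sequences[locus], list(groups), pairs)
            for locus in loci
        }
        for locus in loci:
            per_group, _ = blocks[locus]
            for g in groups:
                names += [f"D:{locus}:{g}", f"pi:{locus}:{g}"]
                values += list(per_group[g])
        for locus in loci:
            _, per_pair = blocks[locus]
            for ga, gb in pairs:
                names.append(f"phiST:{locus}:{ga}|{gb}")
                values.append(per_pair[(ga, gb)])
        n_seq = len(loci) * len(groups) * 2 + len(loci) * len(pairs)
        if len(loci) == 4:
            assert n_seq == 56, "sequence block layout must total 56 statistics"

    if mode in ("aflp", "combined"):
        # pair statistics are undefined (NaN sentinels) when the marker
        # panel is monomorphic for a pair; such panels carry no
        # differentiation signal, so the assembled vector maps them to 0
        # rather than discarding the whole simulation
        def _z(x: float) -> float:
            return 0.0 if math.isnan(x) else x

        by_group = {g: dataset.aflp[dataset.aflp_groups == g] for g in groups}
        for g in groups:
            names.append(f"aflpH:{g}")
            values.append(aflp_heterozygosity(by_group[g]))
        pair_stats = {p: aflp_fst_pair(by_group[p[0]], by_group[p[1]]) for p in pairs}
        for ga, gb in pairs:
            names.append(f"aflpFst:{ga}|{gb}")
            values.append(_z(pair_stats[(ga, gb)][0]))
        for ga, gb in pairs:
            names.append(f"aflpFstSD:{ga}|{gb}")
            values.append(_z(pair_stats[(ga, gb)][1]))
        for ga, gb in pairs:
            names.append(f"jaccard:{ga}|{gb}")
            values.append(_z(jaccard_distance(by_group[ga], by_group[gb])))
        assert len(groups) + 3 * len(pairs) == 22, "AFLP block layout must total 22"

    return pd.Series(values, index=names, dtype=float)
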