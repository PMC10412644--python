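"""f-statistics on group allele frequencies with weighted block jackknife.

Implements the f2/f3/f4 family of drift statistics, the f4-ratio admixture
proportion estimator, a constrained-least-squares admixture-weight solver
in the spirit of qpAdm, and a regional continuity scan based on outgroup
f3 shared drift.

Estimators are simple per-site moment averages:

    f2(A, B)       = mean (pA - pB)^2
    f3(O; A, B)    = mean (pO - pA)(pO - pB)
    f4(A, B; C, D) = mean (pA - pB)(pC - pD)

computed over every site where all populations involved are observed
("allsnps"-style site usage: no global intersection). No small-sample or
inbreeding corrections are applied — all comparative uses here are of
pseudohaploid data where within-individual heterozygosity is unobservable,
which is a documented divergence from AdmixTools numerics.

Standard errors come from a weighted delete-one-block jackknife over
contiguous genomic blocks (default 0.05 Morgans, 5 Mb physical fallback),
with Busing-style weighting for unequal block sizes that reduces to the
classic delete-one formula when block sizes are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_store import GroupFreqs, SnpPanel

DEFAULT_BLOCK_MORGANS = 0.05
DEFAULT_BLOCK_BP = 5_000_000
Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedStatisticError(ValueError):
    """No site is jointly observed for the populations requested."""


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """Assignment of every panel site to a contiguous genomic block."""

    block_index: np.ndarray  # int, per site
    n_blocks: int

    def __post_init__(self) -> None:
        self.block_index = np.asarray(self.block_index, dtype=np.int64)
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.block_index.size and (
                self.block_index.min() < 0
                or self.block_index.max() >= self.n_blocks):
            raise ValueError("block index out of range")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.block_index, minlength=self.n_blocks)


def make_blocks(panel: SnpPanel,
                block_size_morgans: float = DEFAULT_BLOCK_MORGANS,
                fallback_bp: int = DEFAULT_BLOCK_BP) -> BlockSpec:
    """Greedy contiguous blocks of at most ``block_size_morgans`` genetic
    length, falling back to ``fallback_bp`` physical length on chromosomes
    without genetic positions. A new chromosome always starts a new block.
    """
    chrom = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy(dtype=float)
    gpos = panel.sites["genetic_pos"].to_numpy(dtype=float)
    n = panel.n_sites
    idx = np.zeros(n, dtype=np.int64)
    block = -1
    start_val = 0.0
    use_genetic = False
    prev_chrom = None
    for s in range(n):
        if chrom[s] != prev_chrom:
            prev_chrom = chrom[s]
            # genetic positions are used for a chromosome only if present
            # (non-NaN, not all-zero beyond the first site is not required)
            chrom_mask = chrom == chrom[s]
            use_genetic = not np.isnan(gpos[chrom_mask]).any()
            block += 1
            start_val = gpos[s] if use_genetic else pos[s]
        else:
            val = gpos[s] if use_genetic else pos[s]
            limit = block_size_morgans if use_genetic else fallback_bp
            if val - start_val > limit:
                block += 1
                start_val = val
        idx[s] = block
    return BlockSpec(idx, block + 1 if n else 1)


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

@dataclass
class FStat:
    """An f2/f3/f4 estimate with per-block sums and jackknife uncertainty."""

    kind: str
    pops: tuple[str, ...]
    estimate: float
    block_sums: np.ndarray
    block_counts: np.ndarray
    se: float
    z: float
    n_snps: int

    @property
    def n_blocks_used(self) -> int:
        return int((self.block_counts > 0).sum())

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    def leave_one_out(self) -> np.ndarray:
        """Leave-one-block-out estimates, one per non-empty block."""
        used = self.block_counts > 0
        S, N = self.block_sums.sum(), self.block_counts.sum()
        return ((S - self.block_sums[used])
                / (N - self.block_counts[used]))


def weighted_jackknife(estimate: float, loo: np.ndarray,
                       weights: np.ndarray) -> tuple[float, float]:
    """Weighted delete-one-block jackknife (Busing-style) SE and Z.

    ``loo`` are the leave-one-block-out estimates and ``weights`` the block
    sizes m_j. With equal weights this reduces to the classic delete-one
    jackknife variance (g-1)/g * sum (loo_j - mean)^2.
    """
    loo = np.asarray(loo, float)
    m = np.asarray(weights, float)
    g = loo.size
    if g < 2:
        raise ValueError("jackknife needs at least 2 non-empty blocks")
    n = m.sum()
    h = n / m
    theta_j = g * estimate - ((1.0 - m / n) * loo).sum()
    tau = h * estimate - (h - 1.0) * loo
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    se = float(np.sqrt(var))
    z = estimate / se if se > 0 else np.inf * np.sign(estimate) if estimate else 0.0
    return se, float(z)


def _block_stat(kind: str, pops: tuple[str, ...], prod: np.ndarray,
                mask: np.ndarray, blocks: BlockSpec) -> FStat:
    if not mask.any():
        raise UndefinedStatisticError(
            f"{kind}{pops}: no jointly observed site")
    bidx = blocks.block_index[mask]
    sums = np.bincount(bidx, weights=prod[mask], minlength=blocks.n_blocks)
    counts = np.bincount(bidx, minlength=blocks.n_blocks)
    n = int(counts.sum())
    est = float(sums.sum() / n)
    used = counts > 0
    if used.sum() >= 2:
        loo = (sums.sum() - sums[used]) / (n - counts[used])
        se, z = weighted_jackknife(est, loo, counts[used])
    else:
        se, z = np.nan, np.nan
    return FStat(kind, pops, est, sums, counts, se, z, n)


def _freq_rows(freqs: GroupFreqs, *names: str) -> tuple[np.ndarray, ...]:
    f = freqs.freq
    return tuple(f[freqs.index_of(p)] for p in names)


def f4(freqs: GroupFreqs, a: str, b: str, c: str, d: str,
       blocks: BlockSpec) -> FStat:
    """f4(A, B; C, D): zero under treeness of ((A,B),(C,D))."""
    pa, pb, pc, pd_ = _freq_rows(freqs, a, b, c, d)
    mask = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(pc) | np.isnan(pd_))
    prod = np.where(mask, (pa - pb) * (pc - pd_), 0.0)
    return _block_stat("f4", (a, b, c, d), prod, mask, blocks)


def f3_outgroup(freqs: GroupFreqs, o: str, a: str, b: str,
                blocks: BlockSpec) -> FStat:
    """Outgroup f3(O; A, B): shared drift of A and B since divergence from O."""
    po, pa, pb = _freq_rows(freqs, o, a, b)
    mask = ~(np.isnan(po) | np.isnan(pa) | np.isnan(pb))
    prod = np.where(mask, (po - pa) * (po - pb), 0.0)
    return _block_stat("f3", (o, a, b), prod, mask, blocks)


def f2(freqs: GroupFreqs, a: str, b: str, blocks: BlockSpec) -> FStat:
    po, pb = _freq_rows(freqs, a, b)
    mask = ~(np.isnan(po) | np.isnan(pb))
    prod = np.where(mask, (po - pb) ** 2, 0.0)
    return _block_stat("f2", (a, b), prod, mask, blocks)


def jackknife(block_sums: np.ndarray, block_counts: np.ndarray,
              ) -> tuple[float, float]:
    """SE and Z of a ratio-of-sums statistic from its per-block pieces."""
    sums = np.asarray(block_sums, float)
    counts = np.asarray(block_counts, float)
    used = counts > 0
    if used.sum() < 2:
        raise ValueError("jackknife needs at least 2 non-empty blocks")
    S, N = sums.sum(), counts.sum()
    est = S / N
    loo = (S - sums[used]) / (N - counts[used])
    return weighted_jackknife(float(est), loo, counts[used])


# ---------------------------------------------------------------------------
# Admixture estimators
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureEstimate:
    """An admixture-proportion estimate with jackknife uncertainty."""

    target: str
    sources: tuple[str, ...]
    weights: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_snps: int
    z: float = np.nan                 # Z for alpha > 0 (f4-ratio)
    residual_stat: float = np.nan     # chi-square fit statistic (weights solver)
    tail_prob: float = np.nan
    df: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.se = np.atleast_1d(np.asarray(self.se, float))
        self.ci_low = np.atleast_1d(np.asarray(self.ci_low, float))
        self.ci_high = np.atleast_1d(np.asarray(self.ci_high, float))

    @property
    def alpha(self) -> float:
        """The first source's weight (the usual single-alpha reading)."""
        return float(self.weights[0])


def f4_ratio(freqs: GroupFreqs, x: str, a: str, b: str, c: str, o: str,
             blocks: BlockSpec, *, min_denominator_z: float = 3.0,
             ) -> AdmixtureEstimate:
    """f4-ratio estimate of the B-related ancestry proportion in X.

        alpha = f4(A, O; X, C) / f4(A, O; B, C)

    Uncertainty is a leave-one-block-out recomputation of the full ratio
    (not the delta method), which stays robust near small denominators.
    The endpoint identities hold by construction: X = B gives alpha = 1,
    X = C gives alpha = 0.
    """
    num = f4(freqs, a, o, x, c, blocks)
    den = f4(freqs, a, o, b, c, blocks)
    if den.estimate == 0.0:
        raise ZeroDivisionError("f4-ratio denominator is exactly zero")
    alpha = num.estimate / den.estimate
    warnings = []
    if abs(den.z) < min_denominator_z:
        warnings.append(
            f"weak denominator: |Z|={abs(den.z):.2f} < {min_denominator_z}")

    used = (num.block_counts > 0) | (den.block_counts > 0)
    Sn, Nn = num.block_sums.sum(), num.block_counts.sum()
    Sd, Nd = den.block_sums.sum(), den.block_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        loo_num = (Sn - num.block_sums[used]) / (Nn - num.block_counts[used])
        loo_den = (Sd - den.block_sums[used]) / (Nd - den.block_counts[used])
        loo = loo_num / loo_den
    weights = (num.block_counts + den.block_counts)[used]
    se, z = weighted_jackknife(alpha, loo, weights)
    return AdmixtureEstimate(
        target=x, sources=(b, c), weights=[alpha, 1.0 - alpha],
        se=[se, se], ci_low=[alpha - Z95 * se, 1.0 - alpha - Z95 * se],
        ci_high=[alpha + Z95 * se, 1.0 - alpha + Z95 * se],
        n_snps=min(num.n_snps, den.n_snps), z=z, warnings=warnings)


def _solve_constrained(A: np.ndarray, y: np.ndarray,
                       Qinv: np.ndarray | None = None) -> np.ndarray:
    """Least squares of y ~ A w subject to sum(w) = 1.

    Substitutes w_k = 1 - sum(w_1..w_{k-1}); with k = 1 the solution is
    the constraint itself.
    """
    m, k = A.shape
    if k == 1:
        return np.array([1.0])
    D = A[:, :-1] - A[:, [-1]]
    r = y - A[:, -1]
    if Qinv is None:
        Qinv = np.eye(m)
    M = D.T @ Qinv @ D
    u = np.linalg.solve(M, D.T @ Qinv @ r)
    return np.concatenate([u, [1.0 - u.sum()]])


def admixture_weights(freqs: GroupFreqs, target: str,
                      sources: tuple[str, ...] | list[str],
                      rights: tuple[str, ...] | list[str],
                      outgroup: str, blocks: BlockSpec,
                      ) -> AdmixtureEstimate:
    """Constrained-least-squares admixture weights (simplified qpAdm).

    Solves, subject to sum(w) = 1, the overdetermined linear system

        f4(R0, Ri; X, O) = sum_j w_j f4(R0, Ri; Sj, O),  i = 1..m

    with the first right population as the fixed base R0. The residual fit
    statistic is a quadratic form in the residuals under the block-jackknife
    covariance of the f4 vector, referred to chi-square with
    df = m - k + 1; its tail probability is the single/few-source rejection
    test. This is not claimed numerically identical to qpAdm.
    """
    sources = tuple(sources)
    rights = tuple(rights)
    k, m = len(sources), len(rights) - 1
    if k < 1:
        raise ValueError("need at least one source")
    if m < k:
        raise ValueError(
            f"need at least {k + 1} right populations for {k} sources")
    r0, ris = rights[0], rights[1:]
    pops = set(sources) | set(rights) | {target, outgroup}
    if len(pops) < len(sources) + len(rights) + 2:
        raise ValueError("target/sources/rights/outgroup must be disjoint")

    y_stats = [f4(freqs, r0, ri, target, outgroup, blocks) for ri in ris]
    a_stats = [[f4(freqs, r0, ri, sj, outgroup, blocks) for sj in sources]
               for ri in ris]
    y = np.array([s.estimate for s in y_stats])
    A = np.array([[s.estimate for s in row] for row in a_stats])
    if np.linalg.matrix_rank(A, tol=1e-12) < k:
        raise ValueError(
            f"rank-deficient design: sources {sources} are collinear over "
            f"the chosen right populations")

    # leave-one-block-out estimates for every statistic in the system
    nb = blocks.n_blocks
    all_stats = y_stats + [s for row in a_stats for s in row]
    used = np.zeros(nb, dtype=bool)
    for s in all_stats:
        used |= s.block_counts > 0
    g = int(used.sum())

    def loo_est(stat: FStat) -> np.ndarray:
        S, N = stat.block_sums.sum(), stat.block_counts.sum()
        return (S - stat.block_sums[used]) / (N - stat.block_counts[used])

    y_loo = np.column_stack([loo_est(s) for s in y_stats])  # g x m
    A_loo = np.empty((g, m, k))
    for i, row in enumerate(a_stats):
        for j, s in enumerate(row):
            A_loo[:, i, j] = loo_est(s)

    w = _solve_constrained(A, y)
    for _ in range(2):
        r_loo = y_loo - np.einsum("gik,k->gi", A_loo, w)
        rbar = r_loo.mean(axis=0)
        Q = (g - 1) / g * (r_loo - rbar).T @ (r_loo - rbar)
        Q += 1e-12 * np.trace(Q) / m * np.eye(m)
        Qinv = np.linalg.inv(Q)
        w = _solve_constrained(A, y, Qinv)

    resid = y - A @ w
    chi2 = float(resid @ Qinv @ resid)
    df = m - k + 1
    tail = float(sps.chi2.sf(chi2, df)) if df > 0 else np.nan

    # per-weight jackknife SE: re-solve each leave-one-block-out system,
    # re-estimating the residual covariance without that block as well —
    # holding the estimated weight matrix fixed across deletions is the
    # classic two-step pitfall that understates the variance
    r_loo = y_loo - np.einsum("gik,k->gi", A_loo, w)
    w_loo = np.empty((g, k))
    for j in range(g):
        sub = np.delete(r_loo, j, axis=0)
        dev = sub - sub.mean(axis=0)
        Qj = (g - 2) / (g - 1) * dev.T @ dev
        Qj += 1e-12 * np.trace(Qj) / m * np.eye(m)
        w_loo[j] = _solve_constrained(A_loo[j], y_loo[j],
                                      np.linalg.inv(Qj))
    counts = np.zeros(nb)
    for s in all_stats:
        counts += s.block_counts
    mw = counts[used]
    se = np.empty(k)
    for jj in range(k):
        se[jj], _ = weighted_jackknife(float(w[jj]), w_loo[:, jj], mw)
    n_snps = min(s.n_snps for s in all_stats)
    return AdmixtureEstimate(
        target=target, sources=sources, weights=w, se=se,
        ci_low=w - Z95 * se, ci_high=w + Z95 * se, n_snps=n_snps,
        residual_stat=chi2, tail_prob=tail, df=df)


# ---------------------------------------------------------------------------
# Continuity scan
# ---------------------------------------------------------------------------

def continuity_scan(freqs: GroupFreqs, test_ids: list[str],
                    anchor: str, outgroup: str, blocks: BlockSpec,
                    ages: dict[str, float] | pd.Series,
                    min_sites: int = 500) -> pd.DataFrame:
    """Outgroup-f3 shared-drift scan against a regional anchor.

    Each test individual (or group) X gets f3(O; X, anchor) with a 95%
    jackknife CI. The oldest individual's lower CI bound is the reference
    line; an individual is flagged discontinuous when its *upper* CI bound
    falls below that line. Individuals with fewer than ``min_sites``
    jointly observed sites are excluded and listed, not flagged.
    """
    if anchor not in freqs.groups:
        raise KeyError(f"anchor {anchor!r} absent from frequency table")
    ages = dict(ages)
    # the anchor against itself is inflated by its own sampling variance
    # (f3 of a unit with itself picks up E[p(1-p)] noise), so it is not a
    # valid test individual
    test_ids = [t for t in test_ids if t != anchor]
    if not test_ids:
        raise ValueError("no test individual distinct from the anchor")
    for t in test_ids:
        if t not in ages or pd.isna(ages[t]):
            raise ValueError(f"test individual {t!r} has no cal BP age")
    rows = []
    for t in test_ids:
        st = f3_outgroup(freqs, outgroup, t, anchor, blocks)
        lo, hi = st.ci95
        rows.append({"id": t, "cal_bp_mid": float(ages[t]),
                     "estimate": st.estimate, "se": st.se,
                     "ci_low": lo, "ci_high": hi, "n_snps": st.n_snps,
                     "excluded": st.n_snps < min_sites})
    df = pd.DataFrame(rows).sort_values(
        "cal_bp_mid", ascending=False, kind="stable").reset_index(drop=True)
    eligible = df.loc[~df["excluded"]]
    if eligible.empty:
        raise ValueError("every test individual fell below the site threshold")
    ref_low = float(eligible.iloc[0]["ci_low"])
    df["reference_ci_low"] = ref_low
    df["discontinuous"] = (~df["excluded"]) & (df["ci_high"] < ref_low)
    return df
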