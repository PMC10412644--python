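"""Conditional nucleotide diversity and the anchor continuity statistic.

Conditional nucleotide diversity (CND) is the per-site pairwise mismatch
rate between two pseudohaploid genomes over the ascertained panel — a
proxy for within-population diversity when the two genomes come from
unrelated members of the same population. Pairs are formed in descending
temporal order, skipping known kin, with a minimum mean-depth filter.

The anchor continuity test conditions on sites heterozygous in a
high-quality diploid "anchor" individual (where the derived-allele
frequency ascertainment makes the anchor's own proportion exactly 0.5)
and tracks the derived-allele proportion at those sites in other
individuals: the proportion stays constant forwards in time along a
continuous lineage but is reduced in individuals sampled before the
anchor or across a population turnover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fstats import Z95, BlockSpec, weighted_jackknife
from .genotype_store import MISSING, GenotypeMatrix, SnpPanel, UNKNOWN


@dataclass
class CndEstimate:
    pair: tuple[str, str]
    n_overlap: int
    mismatch_rate: float
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.mismatch_rate - Z95 * self.se,
                self.mismatch_rate + Z95 * self.se)


def build_cnd_pairs(meta: pd.DataFrame, group: str, *,
                    min_depth: float = 0.1,
                    kin_exclusions: set[frozenset] | None = None,
                    ) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair group members in descending temporal order, avoiding kin.

    Returns (pairs, unpaired). Individuals below ``min_depth`` mean genome
    depth are ineligible. When the next-in-age partner would form a known
    kin pair, the partner is swapped with the following individual.
    Leftovers (odd cohort, or no kin-free partner) are reported unpaired.
    """
    kin = kin_exclusions or set()
    rows = meta.loc[(meta["group"] == group)
                    & (meta["mean_depth"].fillna(0.0) >= min_depth)]
    if len(rows) < 2:
        raise ValueError(
            f"group {group!r} has fewer than 2 eligible individuals")
    order = list(rows.sort_values("cal_bp_mid", ascending=False,
                                  kind="stable")["id"])
    pairs: list[tuple[str, str]] = []
    unpaired: list[str] = []
    while len(order) >= 2:
        first = order.pop(0)
        partner_idx = next(
            (j for j, cand in enumerate(order)
             if frozenset((first, cand)) not in kin), None)
        if partner_idx is None:
            unpaired.append(first)
        else:
            pairs.append((first, order.pop(partner_idx)))
    unpaired.extend(order)
    return pairs, unpaired


def _pair_block_sums(matrix: GenotypeMatrix, pair: tuple[str, str],
                     blocks: BlockSpec) -> tuple[np.ndarray, np.ndarray]:
    i, j = (matrix.index_of(p) for p in pair)
    if matrix.ploidy[i] != 1 or matrix.ploidy[j] != 1:
        raise ValueError(
            f"CND requires pseudohaploid genotypes; run pseudohaploid "
            f"sampling first (pair {pair})")
    a, b = matrix.calls[i], matrix.calls[j]
    overlap = (a != MISSING) & (b != MISSING)
    diff = overlap & (a != b)
    bidx = blocks.block_index
    sums = np.bincount(bidx[overlap], weights=diff[overlap].astype(float),
                       minlength=blocks.n_blocks)
    counts = np.bincount(bidx[overlap], minlength=blocks.n_blocks)
    return sums, counts


def cnd(matrix: GenotypeMatrix, pair: tuple[str, str],
        blocks: BlockSpec) -> CndEstimate:
    """Pairwise mismatch rate with block-jackknife SE for one pair."""
    sums, counts = _pair_block_sums(matrix, pair, blocks)
    n = int(counts.sum())
    if n == 0:
        raise ValueError(f"pair {pair} has no overlapping sites")
    rate = float(sums.sum() / n)
    used = counts > 0
    if used.sum() >= 2:
        loo = (sums.sum() - sums[used]) / (n - counts[used])
        se, _ = weighted_jackknife(rate, loo, counts[used])
    else:
        se = np.nan
    return CndEstimate(tuple(pair), n, rate, se)


def group_cnd(matrix: GenotypeMatrix, pairs: list[tuple[str, str]],
              blocks: BlockSpec) -> tuple[pd.DataFrame, CndEstimate]:
    """Per-pair CND plus a site-count-weighted pooled group estimate.

    The pooled estimate (total mismatches over total overlap, jackknifed
    over blocks pooling all pairs) is an extension of the per-pair
    statistic, labelled as such in outputs.
    """
    if not pairs:
        raise ValueError("no pairs")
    rows = []
    pooled_sums = np.zeros(blocks.n_blocks)
    pooled_counts = np.zeros(blocks.n_blocks)
    for pair in pairs:
        est = cnd(matrix, pair, blocks)
        lo, hi = est.ci95
        rows.append({"id1": pair[0], "id2": pair[1],
                     "n_overlap": est.n_overlap,
                     "mismatch_rate": est.mismatch_rate, "se": est.se,
                     "ci_low": lo, "ci_high": hi})
        sums, counts = _pair_block_sums(matrix, pair, blocks)
        pooled_sums += sums
        pooled_counts += counts
    n = int(pooled_counts.sum())
    rate = float(pooled_sums.sum() / n)
    used = pooled_counts > 0
    loo = (pooled_sums.sum() - pooled_sums[used]) / (n - pooled_counts[used])
    se, _ = weighted_jackknife(rate, loo, pooled_counts[used])
    pooled = CndEstimate(("pooled", "pooled"), n, rate, se)
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# Anchor continuity
# ---------------------------------------------------------------------------

@dataclass
class AnchorResult:
    anchor: str
    n_conditioned: int
    table: pd.DataFrame  # id, proportion, se, ci_low, ci_high, n_sites, flagged


def anchor_condition(matrix: GenotypeMatrix, anchor: str,
                     panel: SnpPanel | None = None) -> np.ndarray:
    """Indices of sites heterozygous in the (diploid) anchor individual.

    Requires a polarized panel when one is given: sites with an unknown
    ancestral allele are excluded. A pseudohaploid anchor is rejected —
    heterozygosity is unobservable at ploidy 1.
    """
    i = matrix.index_of(anchor)
    if matrix.ploidy[i] == 1:
        raise ValueError(
            f"anchor {anchor!r} is pseudohaploid; heterozygosity is "
            f"unobservable — use a diploid anchor")
    het = matrix.calls[i] == 1
    if panel is not None:
        het &= (panel.sites["ancestral"] != UNKNOWN).to_numpy()
    sites = np.flatnonzero(het)
    if sites.size == 0:
        warnings.warn(f"anchor {anchor!r} has no usable heterozygous site")
    return sites


def anchor_proportion(matrix: GenotypeMatrix, conditioned: np.ndarray,
                      test_ids: list[str], blocks: BlockSpec,
                      anchor: str = "") -> AnchorResult:
    """Derived-allele proportion at anchor-conditioned sites per individual.

    The proportion is derived alleles over called alleles at conditioned
    sites the individual covers, with block-jackknife SE. Individuals with
    zero overlap are flagged and excluded from the table. An anchor tested
    against itself returns exactly 0.5 (heterozygote definition).
    """
    conditioned = np.asarray(conditioned, dtype=int)
    if conditioned.size == 0:
        raise ValueError("conditioned site set is empty")
    bidx = blocks.block_index[conditioned]
    rows = []
    flagged = []
    for ind in test_ids:
        i = matrix.index_of(ind)
        calls = matrix.calls[i, conditioned]
        obs = calls != MISSING
        if not obs.any():
            flagged.append(ind)
            continue
        ploidy = float(matrix.ploidy[i])
        num = np.bincount(bidx[obs], weights=calls[obs].astype(float),
                          minlength=blocks.n_blocks)
        den = np.bincount(bidx[obs], minlength=blocks.n_blocks) * ploidy
        prop = float(num.sum() / den.sum())
        used = den > 0
        if used.sum() >= 2:
            loo = (num.sum() - num[used]) / (den.sum() - den[used])
            se, _ = weighted_jackknife(prop, loo, den[used])
        else:
            se = np.nan
        rows.append({"id": ind, "proportion": prop, "se": se,
                     "ci_low": prop - Z95 * se, "ci_high": prop + Z95 * se,
                     "n_sites": int(obs.sum())})
    table = pd.DataFrame(rows)
    table.attrs["flagged_no_overlap"] = flagged
    return AnchorResult(anchor, int(conditioned.size), table)
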