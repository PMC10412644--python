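"""Synthetic data with known ground truth for every pipeline stage.

The primary engine is the Balding-Nichols drift model on an explicit
admixture graph: root allele frequencies are drawn Uniform(0.05, 0.95)
per site (mimicking common-SNP ascertainment), a child at drift distance
F from its parent draws Beta(p(1-F)/F, (1-p)(1-F)/F), and an admixture
node mixes its two parents' frequencies as alpha * p_P + (1 - alpha) * p_Q.
Closed-form moments (E[f2] between two leaves at drift F from a shared
parent is the summed Beta variance) make exact oracles possible, which a
coalescent simulator would not give.

Also provided: individual genotype sampling (diploid Binomial(2, p) or
pseudohaploid Bernoulli(p), with i.i.d. missingness and symmetric
allele-flip error), a 1-D stepping-stone admixture cline, Mendelian
pedigree simulation for the kinship catalog, and tiny raster fixtures
whose least-cost answers are known analytically or by exhaustive search.

Every generator is deterministic under its seed and ships a
:class:`SyntheticTruth` sufficient to score the downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_store import (MISSING, GenotypeMatrix, SnpPanel, make_meta)
from .geodist import Raster, vertical_factor

#: Kinship coefficient phi per relationship label.
RELATIONSHIP_PHI = {
    "identical": 0.5,
    "parent-offspring": 0.25,
    "full-sibs": 0.25,
    "half-sibs": 0.125,
    "grandparent-grandchild": 0.125,
    "avuncular": 0.125,
    "double-first-cousins": 0.125,
    "unrelated": 0.0,
}

DEFAULT_PANEL_MORGANS = 5.0  # total genetic map length of the synthetic panel


@dataclass
class SyntheticTruth:
    """Generator parameters recorded alongside every synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Admixture graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphNode:
    parents: tuple[str, ...] = ()   # 0 = root, 1 = drift child, 2 = admixed
    drift: float = 0.0              # Balding-Nichols F along the branch
    alpha: float | None = None      # weight on parents[0] for admixed nodes


@dataclass
class GraphSpec:
    """Admixture graph: drift branches plus two-parent admixture nodes."""

    nodes: dict[str, GraphNode]

    def __post_init__(self) -> None:
        roots = [n for n, spec in self.nodes.items() if not spec.parents]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, got {roots}")
        for name, spec in self.nodes.items():
            if not 0.0 <= spec.drift <= 0.5:
                raise ValueError(f"drift F out of [0, 0.5] at node {name!r}")
            for p in spec.parents:
                if p not in self.nodes:
                    raise ValueError(f"unknown parent {p!r} of {name!r}")
            if len(spec.parents) == 2:
                if spec.alpha is None or not 0.0 <= spec.alpha <= 1.0:
                    raise ValueError(f"admixed node {name!r} needs alpha in [0,1]")
            elif len(spec.parents) > 2:
                raise ValueError(f"node {name!r} has more than two parents")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            if state.get(n) == 1:
                raise ValueError(f"cycle through node {n!r}")
            if state.get(n) == 2:
                return
            state[n] = 1
            for p in self.nodes[n].parents:
                visit(p)
            state[n] = 2
            order.append(n)

        for n in self.nodes:
            visit(n)
        return order


def simulate_graph_freqs(graph: GraphSpec, n_sites: int, seed: int,
                         ) -> dict[str, np.ndarray]:
    """Per-node allele frequency vectors under the Balding-Nichols model."""
    rng = np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {}
    for name in graph.topological_order():
        spec = graph.nodes[name]
        if not spec.parents:
            p = rng.uniform(0.05, 0.95, n_sites)
        elif len(spec.parents) == 1:
            p = freqs[spec.parents[0]]
        else:
            a = spec.alpha
            p = a * freqs[spec.parents[0]] + (1 - a) * freqs[spec.parents[1]]
        if spec.drift > 0:
            F = spec.drift
            shape = (1.0 - F) / F
            p = rng.beta(np.maximum(p * shape, 1e-9),
                         np.maximum((1.0 - p) * shape, 1e-9))
        freqs[name] = p
    return freqs


@dataclass
class SamplePlan:
    """How to sample individuals from one graph node."""

    node: str
    n: int
    ploidy: int = 1
    missing_rate: float = 0.0
    error_rate: float = 0.0
    age: float | None = None       # cal BP midpoint tag
    group: str | None = None       # defaults to the node name
    treatment: str = "UDG"
    assay: str = "shotgun"


def make_panel(n_sites: int, morgans: float = DEFAULT_PANEL_MORGANS,
               chrom: str = "1") -> SnpPanel:
    """A synthetic transversion panel on one chromosome.

    Genetic positions are spaced evenly over ``morgans`` so the default
    0.05 M block scheme yields ``morgans / 0.05`` jackknife blocks.
    Alleles are A/C with A ancestral (the polarized convention).
    """
    return SnpPanel(pd.DataFrame({
        "site_id": [f"snp{i}" for i in range(n_sites)],
        "chrom": chrom,
        "pos": np.arange(1, n_sites + 1) * 1000,
        "genetic_pos": np.linspace(0.0, morgans, n_sites, endpoint=False),
        "allele1": "A",
        "allele2": "C",
        "ancestral": "A",
    }))


def _apply_noise(calls: np.ndarray, ploidy: int, missing_rate: float,
                 error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate > 0:
        # each allele copy flips symmetrically with probability e
        keep = rng.binomial(calls, 1.0 - error_rate)
        gain = rng.binomial(ploidy - calls, error_rate)
        calls = (keep + gain).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)
    return calls


def sample_individuals(freqs: Mapping[str, np.ndarray],
                       plans: Sequence[SamplePlan], seed: int,
                       morgans: float = DEFAULT_PANEL_MORGANS,
                       ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame]:
    """Sample genotype matrices from per-node frequencies.

    Diploid calls are Binomial(2, p), pseudohaploid calls Bernoulli(p);
    missingness is i.i.d. per entry and genotyping error flips each allele
    copy symmetrically at the plan's rate.
    """
    rng = np.random.default_rng(seed)
    n_sites = len(next(iter(freqs.values())))
    panel = make_panel(n_sites, morgans)
    ids, ploidies, rows, meta_rows = [], [], [], []
    for plan in plans:
        p = np.asarray(freqs[plan.node])
        group = plan.group or plan.node
        for j in range(plan.n):
            ind = f"{group}_{j}"
            calls = rng.binomial(plan.ploidy, p).astype(np.int8)
            calls = _apply_noise(calls, plan.ploidy, plan.missing_rate,
                                 plan.error_rate, rng)
            ids.append(ind)
            ploidies.append(plan.ploidy)
            rows.append(calls)
            meta_rows.append({"id": ind, "group": group, "sex": "UNKNOWN",
                              "treatment": plan.treatment, "assay": plan.assay,
                              "cal_bp_mid": plan.age, "mean_depth": 1.0})
    matrix = GenotypeMatrix(ids, np.array(ploidies, np.int8), np.array(rows))
    return panel, matrix, make_meta(meta_rows)


def admixture_recovery_graph(alpha: float, drift: float = 0.02) -> GraphSpec:
    """The standard admixture-recovery layout for estimator validation.

    Target X mixes sources S1 and S2 (weight ``alpha`` on S1). Each source
    lineage has a sister reference population (R1, R2) so the right set is
    differentially related to the sources, plus a basal right R0, an extra
    right R3 and a deep outgroup O — the geometry both the f4-ratio
    (A = R1, B = S1, C = S2) and the constrained-least-squares weight
    solver need for power.
    """
    return GraphSpec({
        "root": GraphNode(),
        "O": GraphNode(("root",), drift=0.2),
        "anc": GraphNode(("root",), drift=0.02),
        "L1": GraphNode(("anc",), drift=drift),
        "L2": GraphNode(("anc",), drift=drift),
        "S1": GraphNode(("L1",), drift=drift),
        "R1": GraphNode(("L1",), drift=drift),
        "S2": GraphNode(("L2",), drift=drift),
        "R2": GraphNode(("L2",), drift=drift),
        "R0": GraphNode(("root",), drift=0.05),
        "R3": GraphNode(("anc",), drift=0.05),
        "X": GraphNode(("S1", "S2"), alpha=alpha),
    })


# ---------------------------------------------------------------------------
# Spatial admixture cline
# ---------------------------------------------------------------------------

def simulate_cline(k_demes: int, n_sites: int, seed: int, *,
                   source_drift: float = 0.1,
                   outgroup_drift: float = 0.2,
                   deme_drift: float = 0.0,
                   n_per_deme: int = 2,
                   deme_spacing: float = 1.0,
                   missing_rate: float = 0.0,
                   morgans: float = DEFAULT_PANEL_MORGANS,
                   ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame,
                              dict[str, np.ndarray], SyntheticTruth]:
    """A 1-D stepping-stone admixture cline between two diverged sources.

    Deme d (d = 0..K-1) carries alpha_d = 1 - d/(K-1) ancestry from source
    P (alpha runs linearly from 1 at the P end to 0 at the Q end, 0.5 at
    the midpoint). Deme coordinates are evenly spaced on a line; an
    outgroup population is included for f-statistics.
    """
    if k_demes < 3:
        raise ValueError("need at least 3 demes")
    nodes = {
        "root": GraphNode(),
        "O": GraphNode(("root",), drift=outgroup_drift),
        "anc": GraphNode(("root",), drift=0.02),
        "P": GraphNode(("anc",), drift=source_drift),
        "Q": GraphNode(("anc",), drift=source_drift),
    }
    alphas = {}
    for d in range(k_demes):
        a = 1.0 - d / (k_demes - 1)
        alphas[f"deme{d}"] = a
        nodes[f"deme{d}"] = GraphNode(("P", "Q"), drift=deme_drift, alpha=a)
    graph = GraphSpec(nodes)
    freqs = simulate_graph_freqs(graph, n_sites, seed)

    plans = [SamplePlan("O", 4, ploidy=2, group="Outgroup"),
             SamplePlan("P", 2, ploidy=1, group="SourceP"),
             SamplePlan("Q", 2, ploidy=1, group="SourceQ")]
    for d in range(k_demes):
        plans.append(SamplePlan(f"deme{d}", n_per_deme, ploidy=1,
                                missing_rate=missing_rate, age=7000.0))
    panel, matrix, meta = sample_individuals(freqs, plans, seed + 1, morgans)
    # demes along an axis running away from the P (alpha = 1) end, with a
    # lateral offset so distances to the two source points are not
    # perfectly collinear (as in 2-D geography)
    rng = np.random.default_rng(seed + 2)
    lateral = rng.integers(0, max(2, k_demes // 4), k_demes)
    coords = {f"deme{d}": (d * deme_spacing, float(lateral[d]) * deme_spacing)
              for d in range(k_demes)}
    meta = meta.copy()
    meta["lon"] = [coords.get(g, (np.nan, np.nan))[0] for g in meta["group"]]
    meta["lat"] = [coords.get(g, (np.nan, np.nan))[1] for g in meta["group"]]
    truth = SyntheticTruth(seed, {
        "alpha": alphas, "coords": coords, "k_demes": k_demes,
        "source_drift": source_drift, "n_sites": n_sites})
    return panel, matrix, meta, freqs, truth


# ---------------------------------------------------------------------------
# Temporal scenarios: turnover and a continuous anchor lineage
# ---------------------------------------------------------------------------

def simulate_turnover(n_pre: int, n_post: int, n_sites: int, seed: int, *,
                      split_drift: float = 0.05,
                      outgroup_drift: float = 0.2,
                      oldest_age: float = 10000.0,
                      youngest_age: float = 6000.0,
                      morgans: float = DEFAULT_PANEL_MORGANS,
                      ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame,
                                 SyntheticTruth]:
    """A population-turnover scenario with a known switch time.

    Pre-turnover individuals (older ages) are drawn from one leaf of the
    graph, post-turnover individuals (younger) from a diverged sister
    leaf, so an outgroup-f3 continuity scan against a pre-turnover anchor
    should flag exactly the post-turnover individuals.
    """
    graph = GraphSpec({
        "root": GraphNode(),
        "O": GraphNode(("root",), drift=outgroup_drift),
        "anc": GraphNode(("root",), drift=0.02),
        "local": GraphNode(("anc",), drift=split_drift),
        "incoming": GraphNode(("anc",), drift=split_drift),
    })
    freqs = simulate_graph_freqs(graph, n_sites, seed)
    ages = np.linspace(oldest_age, youngest_age, n_pre + n_post)
    plans = [SamplePlan("O", 4, ploidy=2, group="Outgroup")]
    for j in range(n_pre):
        plans.append(SamplePlan("local", 1, ploidy=1, group=f"pre{j}",
                                age=float(ages[j])))
    for j in range(n_post):
        plans.append(SamplePlan("incoming", 1, ploidy=1, group=f"post{j}",
                                age=float(ages[n_pre + j])))
    panel, matrix, meta = sample_individuals(freqs, plans, seed + 1, morgans)
    truth = SyntheticTruth(seed, {
        "pre_ids": [f"pre{j}_0" for j in range(n_pre)],
        "post_ids": [f"post{j}_0" for j in range(n_post)],
        "split_drift": split_drift, "n_sites": n_sites})
    return panel, matrix, meta, truth


def simulate_anchor_lineage(n_steps: int, n_sites: int, seed: int, *,
                            step_drift: float = 0.01,
                            anchor_step: int | None = None,
                            new_mutation_fraction: float = 0.6,
                            morgans: float = DEFAULT_PANEL_MORGANS,
                            ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame,
                                       SyntheticTruth]:
    """A single population lineage through time, with derived alleles
    arising along the way.

    A fraction of sites get an origin step drawn uniformly along the
    chain: before its origin a derived allele has frequency zero, at the
    origin it enters at a low frequency, and afterwards it drifts. This
    is what makes the anchor statistic asymmetric in time: individuals
    sampled after a diploid anchor keep a derived-allele proportion of
    0.5 at anchor-heterozygous sites (drift is a martingale), while
    individuals from before the anchor miss the alleles that had not yet
    arisen, reducing their proportion.

    One diploid anchor is sampled at ``anchor_step`` (default: middle of
    the chain) and one pseudohaploid individual at every step; ages
    decrease along the chain.
    """
    rng = np.random.default_rng(seed)
    if anchor_step is None:
        anchor_step = n_steps // 2
    origin = np.zeros(n_sites, dtype=int)
    recent = rng.random(n_sites) < new_mutation_fraction
    origin[recent] = rng.integers(1, n_steps, recent.sum())
    p0 = rng.uniform(0.05, 0.95, n_sites)
    entry = rng.uniform(0.05, 0.3, n_sites)  # frequency at mutation origin
    shape = (1.0 - step_drift) / step_drift
    freqs_by_step = []
    p = np.where(origin == 0, p0, 0.0)
    for t in range(n_steps):
        if t > 0:
            drift = p > 0
            p = p.copy()
            p[drift] = rng.beta(np.maximum(p[drift] * shape, 1e-9),
                                np.maximum((1 - p[drift]) * shape, 1e-9))
        p = np.where(recent & (origin == t), entry, p)
        freqs_by_step.append(p)

    freqs = {f"step{t}": freqs_by_step[t] for t in range(n_steps)}
    ages = np.linspace(10000.0, 4000.0, n_steps)
    plans = [SamplePlan(f"step{t}", 1, ploidy=1, group=f"step{t}",
                        age=float(ages[t])) for t in range(n_steps)]
    plans.append(SamplePlan(f"step{anchor_step}", 1, ploidy=2,
                            group="Anchor", age=float(ages[anchor_step])))
    panel, matrix, meta = sample_individuals(freqs, plans, seed + 1, morgans)
    truth = SyntheticTruth(seed, {
        "anchor_id": "Anchor_0", "anchor_step": anchor_step,
        "pre_ids": [f"step{t}_0" for t in range(anchor_step)],
        "post_ids": [f"step{t}_0" for t in range(anchor_step, n_steps)],
        "new_mutation_fraction": new_mutation_fraction})
    return panel, matrix, meta, truth


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def _gamete(diplo: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete per site from a (2, n_sites) haplotype pair."""
    pick = rng.integers(0, 2, diplo.shape[1])
    return diplo[pick, np.arange(diplo.shape[1])]


def simulate_pedigree(relationship: str, pop_freqs: np.ndarray,
                      seed: int, *, missing_rate: float = 0.0,
                      keep_diploid: bool = False,
                      ) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Two individuals with a known relationship under Mendelian transmission.

    Founders draw two haplotypes i.i.d. Bernoulli(p) per site; children
    inherit one random allele from each parent, independently per site.
    The pair is returned pseudohaploid (one random allele per site) unless
    ``keep_diploid``; truth records the kinship coefficient phi.
    """
    if relationship not in RELATIONSHIP_PHI:
        raise ValueError(f"unknown relationship {relationship!r}; "
                         f"catalog: {sorted(RELATIONSHIP_PHI)}")
    rng = np.random.default_rng(seed)
    p = np.asarray(pop_freqs, float)
    n = p.size

    def founder() -> np.ndarray:
        return (rng.random((2, n)) < p).astype(np.int8)

    def child(ma: np.ndarray, pa: np.ndarray) -> np.ndarray:
        return np.stack([_gamete(ma, rng), _gamete(pa, rng)])

    if relationship == "identical":
        x = founder()
        pair = (x, x)
    elif relationship == "parent-offspring":
        x, y = founder(), founder()
        pair = (x, child(x, y))
    elif relationship == "full-sibs":
        x, y = founder(), founder()
        pair = (child(x, y), child(x, y))
    elif relationship == "half-sibs":
        x, y, z = founder(), founder(), founder()
        pair = (child(x, y), child(x, z))
    elif relationship == "grandparent-grandchild":
        gp, y, z = founder(), founder(), founder()
        pair = (gp, child(child(gp, y), z))
    elif relationship == "avuncular":
        x, y, z = founder(), founder(), founder()
        a, b = child(x, y), child(x, y)
        pair = (a, child(b, z))
    elif relationship == "double-first-cousins":
        x, y, w, v = founder(), founder(), founder(), founder()
        a1, a2 = child(x, y), child(x, y)
        b1, b2 = child(w, v), child(w, v)
        pair = (child(a1, b1), child(a2, b2))
    else:  # unrelated
        pair = (founder(), founder())

    ids = [f"{relationship}_0", f"{relationship}_1"]
    if keep_diploid:
        calls = np.stack([h.sum(axis=0) for h in pair]).astype(np.int8)
        ploidy = np.full(2, 2, np.int8)
    else:
        calls = np.stack([_gamete(h, rng) for h in pair]).astype(np.int8)
        ploidy = np.ones(2, np.int8)
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)
    matrix = GenotypeMatrix(ids, ploidy, calls)
    truth = SyntheticTruth(seed, {"relationship": relationship,
                                  "phi": RELATIONSHIP_PHI[relationship]})
    return matrix, truth


def simulate_kin_cohort(pop_freqs: np.ndarray, n_unrelated: int,
                        planted: Sequence[str], seed: int, *,
                        missing_rate: float = 0.0,
                        morgans: float = DEFAULT_PANEL_MORGANS,
                        ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame,
                                   SyntheticTruth]:
    """A single-population cohort with planted related pairs.

    ``planted`` lists relationship labels; each contributes one pair on
    top of ``n_unrelated`` founders, all pseudohaploid. Truth records the
    planted pair ids and their kinship coefficients.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(pop_freqs, float)
    ids, rows = [], []
    truth_pairs = {}
    for j in range(n_unrelated):
        hap = (rng.random(p.size) < p).astype(np.int8)
        ids.append(f"ind{j}")
        rows.append(hap)
    for k, rel in enumerate(planted):
        pair_matrix, _ = simulate_pedigree(
            rel, p, int(rng.integers(0, 2**31 - 1)),
            missing_rate=missing_rate)
        for suffix, calls in zip("ab", pair_matrix.calls):
            ids.append(f"{rel}{k}_{suffix}")
            rows.append(calls)
        truth_pairs[(f"{rel}{k}_a", f"{rel}{k}_b")] = RELATIONSHIP_PHI[rel]
    calls = np.array(rows, dtype=np.int8)
    if missing_rate > 0:
        miss = rng.random((n_unrelated, p.size)) < missing_rate
        calls[:n_unrelated] = np.where(miss, MISSING, calls[:n_unrelated])
    panel = make_panel(p.size, morgans)
    matrix = GenotypeMatrix(ids, np.ones(len(ids), np.int8), calls)
    meta = make_meta([{"id": i, "group": "cohort", "sex": "UNKNOWN",
                       "mean_depth": 1.0} for i in ids])
    truth = SyntheticTruth(seed, {"planted": truth_pairs,
                                  "n_unrelated": n_unrelated})
    return panel, matrix, meta, truth


# ---------------------------------------------------------------------------
# Raster fixtures
# ---------------------------------------------------------------------------

def _octile(nrows: int, ncols: int, src: tuple[int, int],
            cellsize: float = 1.0) -> np.ndarray:
    r0, c0 = src
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    dr = np.abs(rr - r0)
    dc = np.abs(cc - c0)
    return cellsize * (np.maximum(dr, dc) + (math.sqrt(2) - 1)
                       * np.minimum(dr, dc))


def brute_force_path_distance(cost: np.ndarray, elev: np.ndarray | None,
                              src: tuple[int, int], cellsize: float = 1.0,
                              vrma_cut: float = 5.0,
                              slope_param: float = 1.0 / 45.0) -> np.ndarray:
    """Bellman-Ford-style accumulated cost, independent of the Dijkstra path.

    Iterates edge relaxation to a fixed point; used only to build oracle
    truths for small grids.
    """
    nrows, ncols = cost.shape
    acc = np.full((nrows, ncols), math.inf)
    acc[src] = 0.0
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
             if (dr, dc) != (0, 0)]
    for _ in range(nrows * ncols):
        changed = False
        for r in range(nrows):
            for c in range(ncols):
                if math.isinf(acc[r, c]):
                    continue
                for dr, dc in moves:
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                        continue
                    d = cellsize * (math.sqrt(2) if dr and dc else 1.0)
                    vf = 1.0
                    if elev is not None:
                        vf = vertical_factor(elev[r, c], elev[r2, c2], d,
                                             vrma_cut, slope_param)
                        if math.isinf(vf):
                            continue
                    step = d * 0.5 * (cost[r, c] + cost[r2, c2]) * vf
                    if acc[r, c] + step < acc[r2, c2] - 1e-15:
                        acc[r2, c2] = acc[r, c] + step
                        changed = True
        if not changed:
            break
    return acc


RASTER_SCENARIOS = ("uniform", "wall", "ice_corridor", "downhill_valley",
                    "random_small")


def make_raster_fixture(scenario: str, seed: int = 0,
                        ) -> tuple[dict[str, Raster], SyntheticTruth]:
    """Small raster fixtures with known least-cost answers.

    Returns water/ice/elevation rasters plus a truth carrying the source
    cell and the expected accumulated-cost grid (octile closed form for
    the uniform scenario, exhaustive relaxation otherwise).
    """
    rng = np.random.default_rng(seed)
    if scenario not in RASTER_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "uniform":
        water = np.zeros((7, 7))
        ice = np.zeros_like(water)
        elev = np.zeros_like(water)
        src = (3, 3)
        expected = _octile(7, 7, src)
    elif scenario == "wall":
        water = np.zeros((4, 4))
        water[:3, 2] = 100.0  # high-friction wall with a gap at the bottom
        ice = np.zeros_like(water)
        elev = np.zeros_like(water)
        src = (0, 0)
        expected = None
    elif scenario == "ice_corridor":
        water = np.zeros((8, 8))
        ice = np.zeros_like(water)
        ice[1:7, 4] = 1.0  # ice bar with open detours at the edges
        elev = np.zeros_like(water)
        src = (4, 1)
        expected = None
    elif scenario == "downhill_valley":
        water = np.zeros((5, 5))
        ice = np.zeros_like(water)
        # gentle eastward downslope, within the VRMA cutoff
        elev = np.tile(-np.arange(5) * 0.05, (5, 1))
        src = (2, 0)
        expected = None
    else:  # random_small
        water = rng.choice([0.0, 10.0, 30.0, 50.0, 90.0], size=(4, 4))
        ice = (rng.random((4, 4)) < 0.15).astype(float)
        elev = rng.uniform(0, 0.04, (4, 4))
        src = (0, 0)
        expected = None

    from .geodist import add_ice, reclassify_water
    water_r = Raster(water)
    ice_r = Raster(ice)
    elev_r = Raster(elev)
    cost = add_ice(reclassify_water(water_r), ice_r).values
    if expected is None:
        expected = brute_force_path_distance(cost, elev, src)
    truth = SyntheticTruth(seed, {"scenario": scenario, "source": src,
                                  "expected_accumulated": expected})
    return {"water": water_r, "ice": ice_r, "elevation": elev_r}, truth
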