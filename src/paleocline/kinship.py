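"""READ-style pairwise-mismatch kinship and trio genealogy enumeration.

Kinship between two pseudohaploid genomes is estimated from P0, the
per-window proportion of overlapping sites carrying different alleles
(1 Mb non-overlapping physical windows). Mean P0 is normalized by the
cohort median — assuming most pairs are unrelated — giving an expectation
of 1 - phi for kinship coefficient phi, hence 0.5 for identical
individuals/twins, 0.75 for first degree and 0.875 for second degree.
Classes are assigned at the midpoints between those expectations, and a
pair is reported confident when the Z-distance from its normalized mean
to both adjacent class cutoffs exceeds 1.96.

For detected trios, all genealogical models over a fixed relationship
catalog (parent-offspring, full sibs, half sibs, grandparent-grandchild,
avuncular, double first cousins, unrelated) consistent with the observed
degrees, sexes, uniparental haplogroups and age order are enumerated by
constructing candidate pedigrees explicitly and keeping those whose
implied pairwise relationships match.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fstats import weighted_jackknife
from .genotype_store import MISSING, GenotypeMatrix, SnpPanel

DEFAULT_WINDOW_BP = 1_000_000

#: Expected normalized P0 per class (E = 1 - phi).
CLASS_EXPECTATIONS = {
    "identical": 0.5, "first": 0.75, "second": 0.875, "unrelated": 1.0,
}
#: Cutoffs at midpoints of the expectations; a value exactly at a cutoff
#: resolves toward the lower-relatedness side.
CLASS_CUTOFFS = (0.625, 0.8125, 0.9375)
CONFIDENT_Z = 1.96


# ---------------------------------------------------------------------------
# P0
# ---------------------------------------------------------------------------

def pairwise_p0(matrix: GenotypeMatrix, panel: SnpPanel, id1: str, id2: str,
                window_bp: int = DEFAULT_WINDOW_BP,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mismatch proportions (P0) for one pseudohaploid pair.

    Returns (p0 values, overlap counts) over non-empty windows; windows
    with zero overlap are dropped.
    """
    i, j = matrix.index_of(id1), matrix.index_of(id2)
    if matrix.ploidy[i] != 1 or matrix.ploidy[j] != 1:
        raise ValueError("P0 requires pseudohaploid individuals")
    a, b = matrix.calls[i], matrix.calls[j]
    overlap = (a != MISSING) & (b != MISSING)
    if not overlap.any():
        raise ValueError(f"pair ({id1}, {id2}) has zero overlap")
    chrom = panel.sites["chrom"].astype(str)
    pos = panel.sites["pos"].to_numpy()
    # non-overlapping physical windows, restarted per chromosome
    win = pos // window_bp
    widx = pd.factorize(chrom + ":" + pd.Series(win).astype(str))[0]
    nw = int(widx.max()) + 1
    diff = overlap & (a != b)
    counts = np.bincount(widx[overlap], minlength=nw)
    mism = np.bincount(widx[overlap], weights=diff[overlap].astype(float),
                      minlength=nw)
    keep = counts > 0
    return mism[keep] / counts[keep], counts[keep]


def mean_p0(p0: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Overlap-weighted mean of window P0 values and its window-based SE.

    Weighting by window overlap keeps sparse end-of-chromosome windows
    from dominating; the SE is the weighted delete-one-window jackknife.
    """
    p0 = np.asarray(p0, float)
    counts = np.asarray(counts, float)
    n = counts.sum()
    mean = float((p0 * counts).sum() / n)
    if p0.size > 1:
        loo = ((p0 * counts).sum() - p0 * counts) / (n - counts)
        se, _ = weighted_jackknife(mean, loo, counts)
    else:
        se = np.nan
    return mean, se


def normalize_p0(pair_means: dict[tuple[str, str], tuple[float, float]],
                 external_normalizer: float | None = None,
                 ) -> pd.DataFrame:
    """Normalize each pair's mean P0 by the cohort median (READ default).

    The cohort-median normalizer assumes most pairs are unrelated; for
    small cohorts (a single pair) an explicit external value is required.
    SEs are scaled by the same normalizer.
    """
    if external_normalizer is None:
        if len(pair_means) < 2:
            raise ValueError(
                "cohort median needs >= 2 pairs; supply external_normalizer")
        norm = float(np.median([m for m, _ in pair_means.values()]))
    else:
        norm = float(external_normalizer)
    if norm <= 0:
        raise ValueError("normalizer must be positive")
    rows = [{"id1": k[0], "id2": k[1], "mean_p0": m, "se_p0": s,
             "normalized_p0": m / norm, "se_normalized": s / norm,
             "normalizer": norm}
            for k, (m, s) in pair_means.items()]
    return pd.DataFrame(rows)


def classify_degree(normalized_p0: float, se: float,
                    cutoffs: tuple[float, float, float] = CLASS_CUTOFFS,
                    ) -> tuple[str, float, bool]:
    """Class, Z-distance to the adjacent cutoffs, and the confident flag.

    Classes in increasing normalized P0: identical/duplicate, first
    degree, second degree, unrelated; a value exactly at a cutoff goes to
    the lower-relatedness (higher P0) side. ``z_adjacent`` is the minimum
    over the class's bounding cutoffs of |normalized - cutoff| / SE and
    the pair is confident when it exceeds 1.96.
    """
    if not se > 0:
        raise ValueError("SE must be positive")
    c1, c2, c3 = cutoffs
    if normalized_p0 < c1:
        cls, bounds = "identical", (c1,)
    elif normalized_p0 < c2:
        cls, bounds = "first", (c1, c2)
    elif normalized_p0 < c3:
        cls, bounds = "second", (c2, c3)
    else:
        cls, bounds = "unrelated", (c3,)
    z = min(abs(normalized_p0 - b) / se for b in bounds)
    return cls, float(z), bool(z > CONFIDENT_Z)


def _bimodality_flag(means: list[float]) -> bool:
    """Crude structure diagnostic: a large gap splits the mean-P0 values.

    Analyzing two diverged populations in one cohort violates the
    no-structure assumption and shows up as a bimodal mean-P0
    distribution: cross-population pairs sit well above within-population
    ones.
    """
    if len(means) < 8:
        return False
    srt = np.sort(means)
    gaps = np.diff(srt)
    k = int(np.argmax(gaps))
    other = np.delete(gaps, k)
    # a dominant gap separating two substantial clusters; isolated kin
    # pairs (a few low outliers) must not trigger it
    substantial = min(k + 1, len(srt) - k - 1) >= max(2, 0.15 * len(srt))
    return bool(substantial
                and gaps[k] > 5 * np.percentile(other, 90)
                and gaps[k] > 0.02 * np.median(srt))


def kin_screen(matrix: GenotypeMatrix, panel: SnpPanel, meta: pd.DataFrame,
               partition: str = "group", *, min_depth: float = 0.1,
               window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Screen every within-cell pair for kinship.

    Cohorts are screened separately per partition cell (the method assumes
    no population structure within a run). A first pass uses everyone; the
    confirmation pass excludes individuals below ``min_depth`` mean depth
    and recomputes the cohort normalizer. Cells of size < 2 are skipped
    with a notice column; a bimodal mean-P0 distribution raises a
    structure warning flag on the cell.
    """
    depth = dict(zip(meta["id"], meta["mean_depth"].fillna(np.inf)))

    def screen(roster: list[str]) -> pd.DataFrame | None:
        if len(roster) < 2:
            return None
        pair_means = {}
        for x, y in itertools.combinations(roster, 2):
            p0, counts = pairwise_p0(matrix, panel, x, y, window_bp)
            pair_means[(x, y)] = mean_p0(p0, counts)
        if len(pair_means) < 2:
            return None
        return normalize_p0(pair_means)

    results = []
    for cell, members in meta.groupby(partition)["id"]:
        ids = [m for m in members if m in matrix.individuals]
        if len(ids) < 2:
            continue
        # confirmation pass: drop low-depth individuals, renormalize
        confirmed = [i for i in ids if depth[i] >= min_depth]
        table = screen(confirmed) if confirmed != ids else None
        if table is None:
            table = screen(ids)
        if table is None:
            continue
        cls = [classify_degree(r.normalized_p0, r.se_normalized)
               for r in table.itertuples()]
        table["class"] = [t[0] for t in cls]
        table["z_adjacent"] = [t[1] for t in cls]
        table["confident"] = [t[2] for t in cls]
        table["partition"] = cell
        table["structure_warning"] = _bimodality_flag(list(table["mean_p0"]))
        results.append(table)
    if not results:
        raise ValueError("no partition cell had >= 2 screenable individuals")
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# Trio genealogy enumeration
# ---------------------------------------------------------------------------

FIRST_DEGREE_LABELS = ("parent-offspring", "full-sibs")
SECOND_DEGREE_LABELS = ("half-sibs", "grandparent-grandchild", "avuncular",
                        "double-first-cousins")


@dataclass(frozen=True)
class GenealogyModel:
    """One surviving pedigree hypothesis for a trio."""

    ids: tuple[str, str, str]
    relationships: tuple[str, ...]  # one descriptor per pair, canonical order

    def describe(self) -> dict[str, str]:
        pairs = [(self.ids[0], self.ids[1]), (self.ids[0], self.ids[2]),
                 (self.ids[1], self.ids[2])]
        return {f"{a}-{b}": rel for (a, b), rel in zip(pairs, self.relationships)}


class _Pedigree:
    """Union-find over ancestor slots with congruence and sex consistency.

    A slot is a tuple path: ("a",) is individual a, ("a", "m") its mother,
    ("a", "f", "m") its paternal grandmother. Merging two slots merges
    their parent slots recursively (within the two-generation window).
    """

    def __init__(self, base_ids: tuple[str, ...],
                 sexes: dict[str, str]) -> None:
        self.parent: dict[tuple, tuple] = {}
        self.sex: dict[tuple, str] = {}
        self.ok = True
        for b in base_ids:
            for suffix in itertools.chain.from_iterable(
                    itertools.product("mf", repeat=r) for r in range(3)):
                slot = (b, *suffix)
                self.parent[slot] = slot
                if suffix:
                    self.sex[slot] = "XX" if suffix[-1] == "m" else "XY"
                else:
                    self.sex[slot] = sexes.get(b, "UNKNOWN")

    def find(self, slot: tuple) -> tuple:
        while self.parent[slot] != slot:
            self.parent[slot] = self.parent[self.parent[slot]]
            slot = self.parent[slot]
        return slot

    def union(self, a: tuple, b: tuple) -> None:
        if not self.ok:
            return
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        sa, sb = self.sex[ra], self.sex[rb]
        if sa != "UNKNOWN" and sb != "UNKNOWN" and sa != sb:
            self.ok = False
            return
        self.parent[rb] = ra
        if sa == "UNKNOWN":
            self.sex[ra] = sb
        # congruence: merged individuals share parents
        for p in "mf":
            ca, cb = (*ra, p), (*rb, p)
            if ca in self.parent and cb in self.parent:
                self.union(ca, cb)

    def same(self, a: tuple, b: tuple) -> bool:
        return self.find(a) == self.find(b)


def _realizations(label: str, x: str, y: str):
    """Concrete slot-equation sets realizing a relationship label.

    Yields (descriptor, [(slot, slot), ...]) pairs; descriptors carry the
    orientation and linking-parent detail (e.g. 'grandparent-grandchild:
    x->y via m').
    """
    if label == "parent-offspring":
        for parent, child in ((x, y), (y, x)):
            for slot in "mf":
                yield (f"parent-offspring:{parent}->{child}({slot})",
                       [((child, slot), (parent,))])
    elif label == "full-sibs":
        yield (f"full-sibs:{x}~{y}",
               [((x, "m"), (y, "m")), ((x, "f"), (y, "f"))])
    elif label == "half-sibs":
        for slot, word in (("m", "maternal"), ("f", "paternal")):
            yield (f"half-sibs({word}):{x}~{y}",
                   [((x, slot), (y, slot))])
    elif label == "grandparent-grandchild":
        for gp, gc in ((x, y), (y, x)):
            for link in "mf":
                for slot in "mf":
                    yield (f"grandparent-grandchild:{gp}->{gc} via "
                           f"{link}{slot}", [((gc, link, slot), (gp,))])
    elif label == "avuncular":
        for av, nib in ((x, y), (y, x)):
            for link in "mf":
                yield (f"avuncular:{av}->{nib} via {link}",
                       [((av, "m"), (nib, link, "m")),
                        ((av, "f"), (nib, link, "f"))])
    elif label == "double-first-cousins":
        yield (f"double-first-cousins(parallel):{x}~{y}",
               [((x, "m", g), (y, "m", g)) for g in "mf"]
               + [((x, "f", g), (y, "f", g)) for g in "mf"])
        yield (f"double-first-cousins(cross):{x}~{y}",
               [((x, "m", g), (y, "f", g)) for g in "mf"]
               + [((x, "f", g), (y, "m", g)) for g in "mf"])
    elif label == "unrelated":
        yield (f"unrelated:{x}~{y}", [])
    else:
        raise ValueError(f"unknown relationship label {label!r}")


def _implied_label(ped: _Pedigree, x: str, y: str) -> str | None:
    """Canonical relationship implied by a realized pedigree, or None if
    outside the catalog (including compound/inbred configurations)."""
    if ped.same((x,), (y,)):
        return None
    po_xy = any(ped.same((x,), (y, s)) for s in "mf")
    po_yx = any(ped.same((y,), (x, s)) for s in "mf")
    if po_xy and po_yx:
        return None
    shared_m = ped.same((x, "m"), (y, "m"))
    shared_f = ped.same((x, "f"), (y, "f"))
    gp_xy = any(ped.same((x,), (y, a, b)) for a in "mf" for b in "mf")
    gp_yx = any(ped.same((y,), (x, a, b)) for a in "mf" for b in "mf")
    # avuncular: x is a full sib of a parent of y — identity of x with the
    # parent itself (plain parent-offspring) must not count as sibship
    av_xy = any(not ped.same((x,), (y, l))
                and ped.same((x, "m"), (y, l, "m"))
                and ped.same((x, "f"), (y, l, "f")) for l in "mf")
    av_yx = any(not ped.same((y,), (x, l))
                and ped.same((y, "m"), (x, l, "m"))
                and ped.same((y, "f"), (x, l, "f")) for l in "mf")
    # double first cousins: parent pairs are sib pairs, not the *same*
    # parents (which would be full sibs)
    dfc_par = (not shared_m and not shared_f
               and all(ped.same((x, "m", g), (y, "m", g)) for g in "mf")
               and all(ped.same((x, "f", g), (y, "f", g)) for g in "mf"))
    dfc_cross = (not ped.same((x, "m"), (y, "f"))
                 and not ped.same((x, "f"), (y, "m"))
                 and all(ped.same((x, "m", g), (y, "f", g)) for g in "mf")
                 and all(ped.same((x, "f", g), (y, "m", g)) for g in "mf"))
    dfc = dfc_par or dfc_cross
    flags = [po_xy or po_yx, shared_m and shared_f,
             shared_m != shared_f, gp_xy or gp_yx, av_xy or av_yx, dfc]
    labels = ["parent-offspring", "full-sibs", "half-sibs",
              "grandparent-grandchild", "avuncular", "double-first-cousins"]
    active = [lab for lab, fl in zip(labels, flags) if fl]
    if len(active) > 1:
        return None  # compound relationship, outside the catalog
    if active:
        return active[0]
    # any residual ancestor sharing => a catalog-external relationship
    anc = lambda z: {ped.find((z, *s)) for s in itertools.chain.from_iterable(
        itertools.product("mf", repeat=r) for r in range(3))}
    if anc(x) & anc(y):
        return None
    return "unrelated"


#: Expected kinship coefficient per catalog label.
LABEL_PHI = {
    "parent-offspring": 0.25, "full-sibs": 0.25, "half-sibs": 0.125,
    "grandparent-grandchild": 0.125, "avuncular": 0.125,
    "double-first-cousins": 0.125, "unrelated": 0.0,
}


def _pedigree_graph(ped: _Pedigree):
    """Parent map over union-find roots; None entries are founders.

    Roots whose every representative path is at the depth cap have
    unknown parents and count as founders.
    """
    reps: dict[tuple, tuple] = {}
    for slot in ped.parent:
        r = ped.find(slot)
        if r not in reps or len(slot) < len(reps[r]):
            reps[r] = slot
    parents: dict[tuple, tuple | None] = {}
    for r, p in reps.items():
        if len(p) <= 2:
            parents[r] = (ped.find((*p, "m")), ped.find((*p, "f")))
        else:
            parents[r] = None
    return parents


def _acyclic(parents: dict) -> bool:
    state: dict[tuple, int] = {}

    def visit(n) -> bool:
        if state.get(n) == 1:
            return False
        if state.get(n) == 2:
            return True
        state[n] = 1
        if parents.get(n):
            for p in parents[n]:
                if not visit(p):
                    return False
        state[n] = 2
        return True

    return all(visit(n) for n in parents)


def _kinship_phi(parents: dict, a, b, memo: dict) -> float:
    """Kinship coefficient on the realized pedigree (founders unrelated)."""
    key = (a, b) if a <= b else (b, a)
    if key in memo:
        return memo[key]

    def depth(n, seen=()) -> int:
        if parents.get(n) is None or n in seen:
            return 0
        return 1 + max(depth(p, seen + (n,)) for p in parents[n])

    if a == b:
        if parents.get(a) is None:
            phi = 0.5
        else:
            phi = 0.5 * (1.0 + _kinship_phi(parents, *parents[a], memo))
    else:
        x, y = (a, b) if depth(a) >= depth(b) else (b, a)
        if parents.get(x) is None:
            phi = 0.0
        else:
            phi = 0.5 * sum(_kinship_phi(parents, p, y, memo)
                            for p in parents[x])
    memo[key] = phi
    return phi


def _matriline(ped: _Pedigree, z: str) -> set:
    return {ped.find((z,)), ped.find((z, "m")), ped.find((z, "m", "m"))}


def _patriline(ped: _Pedigree, z: str) -> set:
    return {ped.find((z,)), ped.find((z, "f")), ped.find((z, "f", "f"))}


def _y_compatible(h1: str, h2: str) -> bool:
    return h1.startswith(h2) or h2.startswith(h1)


def enumerate_trio_genealogies(
        ids: tuple[str, str, str],
        degrees: dict[frozenset, str],
        sexes: dict[str, str],
        mt_hg: dict[str, str] | None = None,
        y_hg: dict[str, str] | None = None,
        age_intervals: dict[str, tuple[float, float]] | None = None,
        ) -> list[GenealogyModel]:
    """All catalog genealogies consistent with degrees, sexes, haplogroups
    and age order.

    ``degrees`` maps each unordered pair to 'first', 'second' or
    'unrelated'. mtDNA: an all-maternal path between two individuals
    requires identical mt haplogroups, and differing mt haplogroups forbid
    such a path. Y: analogous over paternal paths among XY members, with
    truncated labels compatible when one is a prefix of the other. Ages
    (cal BP intervals, larger = older): a parent or grandparent may not be
    entirely more recent than the descendant. Structurally impossible
    models (e.g. an XX father) are excluded at construction time.
    """
    mt_hg = mt_hg or {}
    y_hg = y_hg or {}
    age_intervals = age_intervals or {}
    a, b, c = ids
    pairs = [(a, b), (a, c), (b, c)]
    options_per_pair = []
    for x, y in pairs:
        deg = degrees[frozenset((x, y))]
        labels = {"first": FIRST_DEGREE_LABELS,
                  "second": SECOND_DEGREE_LABELS,
                  "unrelated": ("unrelated",)}[deg]
        opts = [r for lab in labels for r in _realizations(lab, x, y)]
        options_per_pair.append(opts)

    surviving: dict[tuple[str, ...], GenealogyModel] = {}
    for combo in itertools.product(*options_per_pair):
        ped = _Pedigree(ids, sexes)
        for _, equations in combo:
            for s1, s2 in equations:
                ped.union(s1, s2)
        if not ped.ok:
            continue
        parents = _pedigree_graph(ped)
        if not _acyclic(parents):
            continue
        # implied relationships must match the assigned labels exactly,
        # including the kinship coefficient (rejects compound pedigrees
        # where extra ancestry paths inflate relatedness)
        consistent = True
        memo: dict = {}
        for (x, y), (desc, _) in zip(pairs, combo):
            implied = _implied_label(ped, x, y)
            if implied is None or not desc.startswith(implied):
                consistent = False
                break
            phi = _kinship_phi(parents, ped.find((x,)), ped.find((y,)), memo)
            if abs(phi - LABEL_PHI[implied]) > 1e-9:
                consistent = False
                break
        if not consistent:
            continue
        if not _check_uniparental_and_age(ped, pairs, mt_hg, y_hg,
                                          sexes, age_intervals):
            continue
        key = tuple(desc for desc, _ in combo)
        surviving.setdefault(key, GenealogyModel(ids, key))
    return list(surviving.values())


def _check_uniparental_and_age(ped, pairs, mt_hg, y_hg, sexes,
                               age_intervals) -> bool:
    for x, y in pairs:
        maternal_path = bool(_matriline(ped, x) & _matriline(ped, y))
        if maternal_path and x in mt_hg and y in mt_hg \
                and mt_hg[x] != mt_hg[y]:
            return False
        if sexes.get(x) == "XY" and sexes.get(y) == "XY":
            paternal_path = bool(_patriline(ped, x) & _patriline(ped, y))
            if paternal_path and x in y_hg and y in y_hg \
                    and not _y_compatible(y_hg[x], y_hg[y]):
                return False
        # age order on realized ancestor-descendant links
        for anc_id, desc_id in ((x, y), (y, x)):
            if anc_id not in age_intervals or desc_id not in age_intervals:
                continue
            is_parent = any(ped.same((anc_id,), (desc_id, s)) for s in "mf")
            is_gp = any(ped.same((anc_id,), (desc_id, u, v))
                        for u in "mf" for v in "mf")
            if is_parent or is_gp:
                lo_a, hi_a = age_intervals[anc_id]
                lo_d, hi_d = age_intervals[desc_id]
                if hi_a < lo_d:  # ancestor entirely more recent
                    return False
    return True
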