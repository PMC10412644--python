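"""Data model and I/O for ascertained SNP panels and (pseudo)haploid genotypes.

The central objects are :class:`SnpPanel` (an ascertained biallelic site
list), :class:`GenotypeMatrix` (individuals x sites allele-2 / derived-allele
counts with per-individual ploidy) and the individual metadata table.
Pseudohaploid individuals — the standard representation for low-coverage
ancient DNA, where a single allele is drawn per site and heterozygosity is
unobservable — are represented natively with ploidy 1 rather than as forced
homozygous diploids.

File formats: unpacked text EIGENSTRAT (.geno/.snp/.ind) and a TSV metadata
table. Packed binary EIGENSTRAT is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Matches the EIGENSTRAT '9'
#: convention so matrices round-trip through text files unchanged.
MISSING: int = 9

#: Sentinel for an unknown ancestral allele.
UNKNOWN: str = "N"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns of the individual metadata table, in canonical order.
META_COLUMNS = (
    "id", "group", "sex", "treatment", "assay", "cal_bp_mid",
    "lat", "lon", "mt_hg", "y_hg", "mean_depth",
)


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, bad character, ...)."""


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


def is_transition(a1: str, a2: str) -> bool:
    """True for A<->G and C<->T substitutions."""
    pair = {a1, a2}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for A/T and C/G sites, which are their own strand complement."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SnpPanel:
    """Ascertained biallelic site list.

    ``sites`` holds one row per SNP with columns ``site_id, chrom, pos,
    genetic_pos, allele1, allele2, ancestral``; positions are 1-based bp,
    genetic positions Morgans. Sites are sorted by (chrom, pos) with no
    duplicates; ``ancestral`` is one of the two alleles or :data:`UNKNOWN`.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["site_id", "chrom", "pos", "genetic_pos",
                    "allele1", "allele2", "ancestral"]
        missing = [c for c in required if c not in self.sites.columns]
        if missing:
            raise InvariantError(f"panel missing columns {missing}")
        s = self.sites.reset_index(drop=True)
        if (s["allele1"] == s["allele2"]).any():
            bad = int(np.argmax((s["allele1"] == s["allele2"]).to_numpy()))
            raise InvariantError(f"allele1 == allele2 at site index {bad}")
        key = list(zip(s["chrom"], s["pos"]))
        if sorted(key, key=lambda t: (str(t[0]), int(t[1]))) != key:
            raise InvariantError("sites not sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise InvariantError("duplicate (chrom, pos) in panel")
        ok = (s["ancestral"] == s["allele1"]) | (s["ancestral"] == s["allele2"]) \
            | (s["ancestral"] == UNKNOWN)
        if not ok.all():
            bad = int(np.argmax(~ok.to_numpy()))
            raise InvariantError(f"ancestral not in alleles at site index {bad}")
        self.sites = s

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "SnpPanel":
        """New panel keeping sites where ``mask`` is True (site order kept)."""
        return SnpPanel(self.sites.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def transversion_mask(self) -> np.ndarray:
        a1 = self.sites["allele1"].to_numpy()
        a2 = self.sites["allele2"].to_numpy()
        return np.array([not is_transition(x, y) for x, y in zip(a1, a2)])


@dataclass
class GenotypeMatrix:
    """Individuals x sites matrix of allele-2 (or derived) allele counts.

    ``calls[i, s]`` is in ``{0..ploidy[i]}`` or :data:`MISSING`. ``ploidy``
    is 1 for pseudohaploid individuals and 2 for diploids.
    """

    individuals: list[str]
    ploidy: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.individuals) != len(set(self.individuals)):
            raise InvariantError("duplicate individual ids")
        if self.calls.shape[0] != len(self.individuals):
            raise InvariantError("calls row count != individual count")
        if self.ploidy.shape != (len(self.individuals),):
            raise InvariantError("ploidy length != individual count")
        if not np.isin(self.ploidy, [1, 2]).all():
            raise InvariantError("ploidy must be 1 or 2")
        obs = self.calls != MISSING
        if (self.calls[obs] < 0).any():
            raise InvariantError("negative genotype call")
        over = obs & (self.calls > self.ploidy[:, None])
        if over.any():
            i, s = np.argwhere(over)[0]
            raise InvariantError(
                f"call {self.calls[i, s]} exceeds ploidy {self.ploidy[i]} "
                f"for individual {self.individuals[i]!r} at site {s}")

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def index_of(self, ind_id: str) -> int:
        try:
            return self.individuals.index(ind_id)
        except ValueError:
            raise KeyError(f"unknown individual {ind_id!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.ploidy.copy(),
                              self.calls[:, np.asarray(mask, bool)])

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.index_of(i) for i in ids]
        return GenotypeMatrix(list(ids), self.ploidy[idx], self.calls[idx])


@dataclass
class GroupFreqs:
    """Per-group per-site derived-allele counts, totals and frequencies.

    ``counts[g, s]`` sums derived alleles over non-missing calls of group
    members; ``totals[g, s]`` sums their ploidies. ``freq`` is NaN where a
    group has no data at a site (flagged absent).
    """

    groups: list[str]
    counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.groups = list(self.groups)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.totals = np.asarray(self.totals, dtype=np.float64)
        if self.counts.shape != self.totals.shape:
            raise InvariantError("counts/totals shape mismatch")
        if self.counts.shape[0] != len(self.groups):
            raise InvariantError("group count mismatch")
        if (self.counts > self.totals).any():
            raise InvariantError("derived count exceeds allele total")

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.counts / self.totals, np.nan)

    def index_of(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None


def make_meta(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a metadata table with the canonical columns from row dicts."""
    df = pd.DataFrame(list(rows))
    for c in META_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[list(META_COLUMNS)]
    if df["id"].duplicated().any():
        raise InvariantError("duplicate individual id in metadata")
    bad_y = df["y_hg"].notna() & (df["sex"] != "XY")
    if bad_y.any():
        raise InvariantError("y_hg present for a non-XY individual")
    return df


def read_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str})
    return make_meta(df.to_dict("records"))


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

_SEX_TO_EIG = {"XX": "F", "XY": "M", "UNKNOWN": "U"}
_EIG_TO_SEX = {"F": "XX", "M": "XY", "U": "UNKNOWN"}


def read_eigenstrat(geno_path: str | Path, snp_path: str | Path,
                    ind_path: str | Path, *,
                    pseudohaploid_marker: str = "_PH",
                    ) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame]:
    """Read unpacked text EIGENSTRAT triplet.

    ``.geno`` rows are SNPs, columns individuals, characters 0/1/2/9 with 9
    mapping to :data:`MISSING`. Individuals whose ``.ind`` group label ends
    with ``pseudohaploid_marker`` get ploidy 1 (the marker is stripped from
    the stored group); everyone else is diploid.
    """
    ind_rows = []
    for lineno, line in enumerate(Path(ind_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise FormatError(f"{ind_path}:{lineno}: expected 'id sex group'")
        ind_rows.append(parts)
    if not ind_rows:
        raise FormatError(f"{ind_path}: no individuals")

    ids = [r[0] for r in ind_rows]
    sexes = [_EIG_TO_SEX.get(r[1], "UNKNOWN") for r in ind_rows]
    raw_groups = [r[2] for r in ind_rows]
    ploidy = np.array([1 if g.endswith(pseudohaploid_marker) else 2
                       for g in raw_groups], dtype=np.int8)
    groups = [g.removesuffix(pseudohaploid_marker) for g in raw_groups]

    snp_rows = []
    for lineno, line in enumerate(Path(snp_path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise FormatError(f"{snp_path}:{lineno}: expected 6 columns")
        snp_rows.append(parts)
    panel = SnpPanel(pd.DataFrame({
        "site_id": [r[0] for r in snp_rows],
        "chrom": [r[1] for r in snp_rows],
        "pos": [int(r[3]) for r in snp_rows],
        "genetic_pos": [float(r[2]) for r in snp_rows],
        "allele1": [r[4] for r in snp_rows],
        "allele2": [r[5] for r in snp_rows],
        "ancestral": [UNKNOWN] * len(snp_rows),
    }))

    geno_lines = [ln for ln in Path(geno_path).read_text().splitlines() if ln]
    if len(geno_lines) != panel.n_sites:
        raise FormatError(
            f"{geno_path}: {len(geno_lines)} rows but {panel.n_sites} SNPs "
            f"in {snp_path}")
    calls = np.full((len(ids), panel.n_sites), MISSING, dtype=np.int8)
    for s, line in enumerate(geno_lines):
        if len(line) != len(ids):
            raise FormatError(
                f"{geno_path}: line {s + 1} has width {len(line)}, "
                f"expected {len(ids)} individuals")
        for i, ch in enumerate(line):
            if ch not in "0129":
                raise FormatError(
                    f"{geno_path}: line {s + 1}, column {i + 1}: "
                    f"invalid character {ch!r}")
            calls[i, s] = MISSING if ch == "9" else int(ch)
    over = (calls != MISSING) & (calls > ploidy[:, None])
    if over.any():
        i, s = np.argwhere(over)[0]
        raise FormatError(
            f"{geno_path}: value {calls[i, s]} for pseudohaploid individual "
            f"{ids[i]!r} at SNP row {s + 1}")

    matrix = GenotypeMatrix(ids, ploidy, calls)
    meta = make_meta([{"id": i, "group": g, "sex": x}
                      for i, g, x in zip(ids, groups, sexes)])
    return panel, matrix, meta


def write_eigenstrat(panel: SnpPanel, matrix: GenotypeMatrix,
                     meta: pd.DataFrame, out_prefix: str | Path, *,
                     pseudohaploid_marker: str = "_PH",
                     diploidize: bool = False) -> dict[str, Path]:
    """Write unpacked text EIGENSTRAT triplet; returns the three paths.

    With ``diploidize`` pseudohaploid calls are exported homozygote-coded
    (0/2) with no ploidy marker, for interoperability with tools that
    assume diploid genotypes.
    """
    if matrix.n_ind == 0:
        raise InvariantError("cannot write EIGENSTRAT with zero individuals")
    if panel.n_sites != matrix.n_sites:
        raise InvariantError("panel/matrix site count mismatch")
    out_prefix = Path(out_prefix)
    paths = {ext: out_prefix.with_suffix("." + ext)
             for ext in ("geno", "snp", "ind")}

    meta_by_id = meta.set_index("id")
    with open(paths["ind"], "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            row = meta_by_id.loc[ind]
            group = str(row["group"])
            if matrix.ploidy[i] == 1 and not diploidize:
                group += pseudohaploid_marker
            fh.write(f"{ind}\t{_SEX_TO_EIG.get(row['sex'], 'U')}\t{group}\n")

    with open(paths["snp"], "w") as fh:
        for r in panel.sites.itertuples(index=False):
            gp = 0.0 if pd.isna(r.genetic_pos) else r.genetic_pos
            fh.write(f"{r.site_id}\t{r.chrom}\t{gp:.6f}\t{r.pos}"
                     f"\t{r.allele1}\t{r.allele2}\n")

    calls = matrix.calls
    if diploidize:
        calls = calls.copy()
        hap = matrix.ploidy == 1
        obs = calls[hap] != MISSING
        calls[hap] = np.where(obs, calls[hap] * 2, calls[hap])
    with open(paths["geno"], "w") as fh:
        for s in range(matrix.n_sites):
            fh.write("".join(str(int(c)) for c in calls[:, s]) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Panel construction operations
# ---------------------------------------------------------------------------

def sample_pseudohaploid(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Draw one allele per site per individual, emulating the pseudohaploid
    calling applied to ancient samples and the haploidization of moderns.

    Homozygotes map deterministically (0 -> 0, 2 -> 1); heterozygotes become
    0 or 1 with probability 1/2 each under ``seed``. MISSING is preserved.
    """
    if not (matrix.ploidy == 2).all():
        raise InvariantError("sample_pseudohaploid expects diploid input")
    rng = np.random.default_rng(seed)
    calls = matrix.calls
    out = np.full_like(calls, MISSING)
    obs = calls != MISSING
    out[obs] = (calls[obs] // 2).astype(np.int8)
    het = obs & (calls == 1)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return GenotypeMatrix(matrix.individuals,
                          np.ones(matrix.n_ind, dtype=np.int8), out)


def group_frequencies(matrix: GenotypeMatrix, meta: pd.DataFrame,
                      grouping: str | Mapping[str, str] = "group") -> GroupFreqs:
    """Allele-2 / derived-allele frequencies per group per site.

    ``grouping`` is a metadata column name or an explicit id -> group map.
    Frequency = derived count / non-missing allele total; groups with no
    data at a site carry NaN there.
    """
    if isinstance(grouping, str):
        id_to_group = dict(zip(meta["id"], meta[grouping]))
    else:
        id_to_group = dict(grouping)
    labels = [id_to_group.get(i) for i in matrix.individuals]
    groups = sorted({g for g in labels if g is not None and not pd.isna(g)})
    if not groups:
        raise InvariantError("empty grouping")
    counts = np.zeros((len(groups), matrix.n_sites))
    totals = np.zeros_like(counts)
    obs = matrix.calls != MISSING
    for gi, g in enumerate(groups):
        members = [i for i, lab in enumerate(labels) if lab == g]
        sub = matrix.calls[members]
        sub_obs = obs[members]
        counts[gi] = np.where(sub_obs, sub, 0).sum(axis=0)
        totals[gi] = (sub_obs * matrix.ploidy[members, None]).sum(axis=0)
    return GroupFreqs(groups, counts, totals)


def apply_panel_filters(panel: SnpPanel, matrix: GenotypeMatrix, *,
                        meta: pd.DataFrame | None = None,
                        freq_group: str | None = None,
                        maf_min: float = 0.0,
                        transversions_only: bool = False,
                        treatment_rules: bool = False,
                        ) -> tuple[SnpPanel, GenotypeMatrix]:
    """Apply the panel-construction filters.

    Sites with minor-allele frequency below ``maf_min`` in ``freq_group``
    are removed (the Yoruba MAF >= 0.1 style ascertainment). With
    ``transversions_only`` transition sites (C/T, G/A) are removed
    entirely. With ``treatment_rules`` transition sites are instead masked
    to MISSING for non-UDG individuals only, at individual resolution,
    while UDG and half-UDG individuals keep them.
    """
    keep = np.ones(panel.n_sites, dtype=bool)
    if maf_min > 0:
        if freq_group is None or meta is None:
            raise InvariantError("maf_min > 0 requires freq_group and meta")
        freqs = group_frequencies(matrix, meta)
        gi = freqs.index_of(freq_group)
        f = freqs.freq[gi]
        maf = np.minimum(f, 1.0 - f)
        keep &= np.where(np.isnan(maf), False, maf >= maf_min)
    if transversions_only:
        keep &= panel.transversion_mask()
    out_matrix = matrix.subset_sites(keep)
    out_panel = panel.subset(keep)
    if treatment_rules:
        if meta is None:
            raise InvariantError("treatment_rules requires meta")
        transitions = ~out_panel.transversion_mask()
        treat = dict(zip(meta["id"], meta["treatment"]))
        calls = out_matrix.calls.copy()
        for i, ind in enumerate(out_matrix.individuals):
            if treat.get(ind) == "non-UDG":
                calls[i, transitions] = MISSING
        out_matrix = GenotypeMatrix(out_matrix.individuals,
                                    out_matrix.ploidy, calls)
    return out_panel, out_matrix


@dataclass
class MergeReport:
    n_kept: int = 0
    n_triallelic_dropped: int = 0
    n_ambiguous_dropped: int = 0
    n_irreconcilable_dropped: int = 0


def merge_datasets(datasets: Sequence[tuple[SnpPanel, GenotypeMatrix]],
                   ) -> tuple[SnpPanel, GenotypeMatrix, MergeReport]:
    """Merge datasets on the intersection of (chrom, pos).

    Allele labels are reconciled by swap, and by complement strand-flip at
    unambiguous transversion sites only. Sites whose allele union exceeds
    two are dropped and counted as triallelic; strand-ambiguous sites (A/T,
    C/G) needing a flip, and any other irreconcilable pair, are dropped
    under their own counters — never silently kept.
    """
    if len(datasets) == 0:
        raise InvariantError("no datasets to merge")
    report = MergeReport()
    base_panel, base_matrix = datasets[0]
    cur = base_panel.sites.copy()
    cur_calls = base_matrix.calls.copy()
    cur_inds = list(base_matrix.individuals)
    cur_ploidy = base_matrix.ploidy.copy()

    for panel, matrix in datasets[1:]:
        other = panel.sites
        key_cur = pd.MultiIndex.from_arrays([cur["chrom"], cur["pos"]])
        key_oth = pd.MultiIndex.from_arrays([other["chrom"], other["pos"]])
        common = key_cur.intersection(key_oth)
        idx_cur = np.flatnonzero(key_cur.isin(common))
        pos_oth = {k: j for j, k in enumerate(key_oth)}
        idx_oth = np.array([pos_oth[key_cur[j]] for j in idx_cur], dtype=int)

        keep_rows = []
        flip_rows = []   # positions (into kept list) where calls recode c -> ploidy - c
        for out_j, (jc, jo) in enumerate(zip(idx_cur, idx_oth)):
            a1, a2 = cur["allele1"].iat[jc], cur["allele2"].iat[jc]
            b1, b2 = other["allele1"].iat[jo], other["allele2"].iat[jo]
            if (b1, b2) == (a1, a2):
                keep_rows.append((jc, jo, False))
            elif (b1, b2) == (a2, a1):
                keep_rows.append((jc, jo, True))
            elif is_strand_ambiguous(a1, a2) or is_strand_ambiguous(b1, b2):
                report.n_ambiguous_dropped += 1
            elif not is_transition(a1, a2) and not is_transition(b1, b2) \
                    and set(map(_COMPLEMENT.get, (b1, b2))) == {a1, a2}:
                # strand flip at an unambiguous transversion site
                fb1 = _COMPLEMENT[b1]
                keep_rows.append((jc, jo, fb1 != a1))
            elif len({a1, a2, b1, b2}) > 2:
                report.n_triallelic_dropped += 1
            else:
                report.n_irreconcilable_dropped += 1

        new_sites = cur.iloc[[r[0] for r in keep_rows]].reset_index(drop=True)
        new_cur_calls = cur_calls[:, [r[0] for r in keep_rows]]
        oth_calls = matrix.calls[:, [r[1] for r in keep_rows]].copy()
        swap = np.array([r[2] for r in keep_rows], dtype=bool)
        if swap.any():
            obs = oth_calls[:, swap] != MISSING
            oth_calls[:, swap] = np.where(
                obs, matrix.ploidy[:, None] - oth_calls[:, swap],
                oth_calls[:, swap])
        dup = set(cur_inds) & set(matrix.individuals)
        if dup:
            raise InvariantError(f"individual ids shared between datasets: {sorted(dup)}")
        cur = new_sites
        cur_calls = np.vstack([new_cur_calls, oth_calls])
        cur_inds = cur_inds + list(matrix.individuals)
        cur_ploidy = np.concatenate([cur_ploidy, matrix.ploidy])

    report.n_kept = len(cur)
    return (SnpPanel(cur),
            GenotypeMatrix(cur_inds, cur_ploidy, cur_calls),
            report)


def polarize(panel: SnpPanel, matrix: GenotypeMatrix,
             ancestral_source: str = "panel",
             ) -> tuple[SnpPanel, GenotypeMatrix]:
    """Recode calls to derived-allele counts.

    ``ancestral_source`` is ``"panel"`` (use the panel's ancestral field,
    e.g. chimpanzee-assigned states) or the id of an outgroup individual
    whose homozygous calls define the ancestral allele. Sites without
    ancestral information, or where the outgroup is heterozygous or
    missing, are removed. After polarization allele1 is the ancestral
    allele and calls count the derived allele.
    """
    sites = panel.sites.copy()
    if ancestral_source == "panel":
        anc = sites["ancestral"].to_numpy().copy()
    else:
        i = matrix.index_of(ancestral_source)
        c = matrix.calls[i]
        p = int(matrix.ploidy[i])
        anc = np.where(c == 0, sites["allele1"],
                       np.where(c == p, sites["allele2"], UNKNOWN))
    known = anc != UNKNOWN
    if not known.any():
        raise InvariantError("no ancestral information at any site")
    sites = sites.loc[known].reset_index(drop=True)
    anc = anc[known]
    calls = matrix.calls[:, known].copy()
    flip = anc == sites["allele2"].to_numpy()
    obs = calls[:, flip] != MISSING
    calls[:, flip] = np.where(obs, matrix.ploidy[:, None] - calls[:, flip],
                              calls[:, flip])
    a1 = sites["allele1"].to_numpy().copy()
    a2 = sites["allele2"].to_numpy().copy()
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    sites["allele1"], sites["allele2"] = a1, a2
    sites["ancestral"] = a1
    return SnpPanel(sites), GenotypeMatrix(matrix.individuals,
                                           matrix.ploidy.copy(), calls)
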