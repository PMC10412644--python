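import numpy as np
import pandas as pd
import pytest

from paleocline.genotype_store import (
    MISSING, UNKNOWN, FormatError, GenotypeMatrix, InvariantError, SnpPanel,
    apply_panel_filters, group_frequencies, is_transition, make_meta,
    merge_datasets, polarize, read_eigenstrat, sample_pseudohaploid,
    write_eigenstrat,
)


def _write_triplet(tmp_path, geno_rows, snp_rows, ind_rows):
    (tmp_path / "d.geno").write_text("\n".join(geno_rows) + "\n")
    (tmp_path / "d.snp").write_text("\n".join(snp_rows) + "\n")
    (tmp_path / "d.ind").write_text("\n".join(ind_rows) + "\n")
    return tmp_path / "d.geno", tmp_path / "d.snp", tmp_path / "d.ind"


class TestEigenstratIO:
    def test_read_transcribes_geno_rows(self, tmp_path):
        paths = _write_triplet(
            tmp_path, ["029", "110"],
            ["s1 1 0.0 100 A C", "s2 1 0.001 200 G T"],
            ["a M Grp", "b F Grp", "c U Grp"])
        panel, matrix, meta = read_eigenstrat(*paths)
        expected = np.array([[0, 1], [2, 1], [MISSING, 0]])
        np.testing.assert_array_equal(matrix.calls, expected)
        assert panel.n_sites == 2
        assert list(meta["sex"]) == ["XY", "XX", "UNKNOWN"]

    def test_duplicate_position_rejected(self, tmp_path):
        paths = _write_triplet(
            tmp_path, ["0", "1"],
            ["s1 1 0.0 100 A C", "s2 1 0.001 100 G T"], ["a M Grp"])
        with pytest.raises(InvariantError, match="duplicate"):
            read_eigenstrat(*paths)

    def test_dimension_mismatch_names_file(self, tmp_path):
        paths = _write_triplet(tmp_path, ["01"],
                               ["s1 1 0.0 100 A C", "s2 1 0.0 200 A C"],
                               ["a M G", "b M G"])
        with pytest.raises(FormatError, match="geno"):
            read_eigenstrat(*paths)

    def test_bad_character_located(self, tmp_path):
        paths = _write_triplet(tmp_path, ["0x"],
                               ["s1 1 0.0 100 A C"], ["a M G", "b M G"])
        with pytest.raises(FormatError, match="line 1, column 2"):
            read_eigenstrat(*paths)

    def test_round_trip_identity(self, tmp_path, random_dataset):
        panel, matrix, meta = random_dataset
        write_eigenstrat(panel, matrix, meta, tmp_path / "rt")
        panel2, matrix2, meta2 = read_eigenstrat(
            tmp_path / "rt.geno", tmp_path / "rt.snp", tmp_path / "rt.ind")
        np.testing.assert_array_equal(matrix.calls, matrix2.calls)
        np.testing.assert_array_equal(matrix.ploidy, matrix2.ploidy)
        assert matrix.individuals == matrix2.individuals
        for col in ("site_id", "chrom", "pos", "allele1", "allele2"):
            assert list(panel.sites[col]) == list(panel2.sites[col])
        assert list(meta["group"]) == list(meta2["group"])

    def test_empty_output_rejected(self, tiny_panel):
        empty = GenotypeMatrix([], np.zeros(0, np.int8),
                               np.zeros((0, 5), np.int8))
        with pytest.raises(InvariantError):
            write_eigenstrat(tiny_panel, empty, make_meta([]), "x")

    def test_single_cell_geno_body(self, tmp_path):
        panel = SnpPanel(pd.DataFrame({
            "site_id": ["s"], "chrom": ["1"], "pos": [1],
            "genetic_pos": [0.0], "allele1": ["A"], "allele2": ["C"],
            "ancestral": [UNKNOWN]}))
        matrix = GenotypeMatrix(["a"], np.array([2], np.int8),
                                np.array([[1]], np.int8))
        meta = make_meta([{"id": "a", "group": "G", "sex": "XX"}])
        paths = write_eigenstrat(panel, matrix, meta, tmp_path / "one")
        assert paths["geno"].read_text() == "1\n"


class TestPseudohaploid:
    def test_homozygotes_deterministic_and_seed_reproducible(self):
        calls = np.array([[0, 2, MISSING, 1]], dtype=np.int8)
        m = GenotypeMatrix(["a"], np.array([2], np.int8), calls)
        out1 = sample_pseudohaploid(m, seed=5)
        out2 = sample_pseudohaploid(m, seed=5)
        np.testing.assert_array_equal(out1.calls, out2.calls)
        assert out1.calls[0, 0] == 0 and out1.calls[0, 1] == 1
        assert out1.calls[0, 2] == MISSING
        assert (out1.ploidy == 1).all()

    def test_heterozygote_draw_is_fair(self):
        m = GenotypeMatrix(["a"], np.array([2], np.int8),
                           np.ones((1, 10_000), dtype=np.int8))
        out = sample_pseudohaploid(m, seed=11)
        derived = int(out.calls.sum())
        # Binomial(10000, 0.5) central 99% interval
        assert 4871 <= derived <= 5129

    def test_rejects_pseudohaploid_input(self):
        m = GenotypeMatrix(["a"], np.array([1], np.int8),
                           np.zeros((1, 3), np.int8))
        with pytest.raises(InvariantError):
            sample_pseudohaploid(m, seed=0)


class TestPanelFilters:
    def test_transition_site_dropped(self):
        panel = SnpPanel(pd.DataFrame({
            "site_id": ["s1", "s2"], "chrom": ["1", "1"], "pos": [1, 2],
            "genetic_pos": [0.0, 0.0], "allele1": ["A", "A"],
            "allele2": ["G", "C"], "ancestral": [UNKNOWN, UNKNOWN]}))
        m = GenotypeMatrix(["a"], np.array([2], np.int8),
                           np.array([[1, 1]], np.int8))
        p2, m2 = apply_panel_filters(panel, m, transversions_only=True)
        assert list(p2.sites["site_id"]) == ["s2"]
        assert m2.n_sites == 1

    def test_maf_threshold(self):
        panel = SnpPanel(pd.DataFrame({
            "site_id": ["s1", "s2"], "chrom": ["1", "1"], "pos": [1, 2],
            "genetic_pos": [0.0, 0.0], "allele1": ["A", "A"],
            "allele2": ["C", "C"], "ancestral": [UNKNOWN, UNKNOWN]}))
        # ten diploids: site frequencies 0.05 and 0.5
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = 1
        calls[:5, 1] = 2
        m = GenotypeMatrix([f"i{k}" for k in range(10)],
                           np.full(10, 2, np.int8), calls)
        meta = make_meta([{"id": f"i{k}", "group": "YRI", "sex": "UNKNOWN"}
                          for k in range(10)])
        p2, m2 = apply_panel_filters(panel, m, meta=meta, freq_group="YRI",
                                     maf_min=0.1)
        assert list(p2.sites["site_id"]) == ["s2"]

    def test_unknown_group_rejected(self, random_dataset):
        panel, matrix, meta = random_dataset
        with pytest.raises(KeyError):
            apply_panel_filters(panel, matrix, meta=meta,
                                freq_group="nope", maf_min=0.1)

    def test_treatment_rules_mask_per_individual(self):
        panel = SnpPanel(pd.DataFrame({
            "site_id": ["s1", "s2"], "chrom": ["1", "1"], "pos": [1, 2],
            "genetic_pos": [0.0, 0.0], "allele1": ["A", "A"],
            "allele2": ["G", "C"], "ancestral": [UNKNOWN, UNKNOWN]}))
        m = GenotypeMatrix(["u", "n"], np.array([1, 1], np.int8),
                           np.array([[1, 1], [1, 1]], np.int8))
        meta = make_meta([
            {"id": "u", "group": "G", "sex": "UNKNOWN", "treatment": "UDG"},
            {"id": "n", "group": "G", "sex": "UNKNOWN",
             "treatment": "non-UDG"}])
        _, m2 = apply_panel_filters(panel, m, meta=meta,
                                    treatment_rules=True)
        assert m2.calls[0, 0] == 1          # UDG keeps the transition
        assert m2.calls[1, 0] == MISSING    # non-UDG masked
        assert m2.calls[1, 1] == 1          # transversion untouched

    def test_filter_matches_per_site_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        rows = []
        for i in range(200):
            a1, a2 = rng.choice(list(bases), 2, replace=False)
            rows.append({"site_id": f"s{i}", "chrom": "1", "pos": i + 1,
                         "genetic_pos": 0.0, "allele1": a1, "allele2": a2,
                         "ancestral": UNKNOWN})
        panel = SnpPanel(pd.DataFrame(rows))
        calls = rng.integers(0, 3, (8, 200)).astype(np.int8)
        m = GenotypeMatrix([f"i{k}" for k in range(8)],
                           np.full(8, 2, np.int8), calls)
        meta = make_meta([{"id": f"i{k}", "group": "P", "sex": "UNKNOWN"}
                          for k in range(8)])
        p1, m1 = apply_panel_filters(panel, m, meta=meta, freq_group="P",
                                     maf_min=0.1, transversions_only=True)
        survivors = set(p1.sites["site_id"])
        for i in range(200):
            a1, a2 = panel.sites["allele1"][i], panel.sites["allele2"][i]
            f = calls[:, i].sum() / 16.0
            expect = (not is_transition(a1, a2)) and min(f, 1 - f) >= 0.1
            assert (f"s{i}" in survivors) == expect
        p2, m2 = apply_panel_filters(p1, m1, meta=meta, freq_group="P",
                                     maf_min=0.1, transversions_only=True)
        assert list(p2.sites["site_id"]) == list(p1.sites["site_id"])
        np.testing.assert_array_equal(m1.calls, m2.calls)


class TestMerge:
    def _panel(self, allele_pairs, start=1):
        return SnpPanel(pd.DataFrame({
            "site_id": [f"s{i}" for i in range(len(allele_pairs))],
            "chrom": "1", "pos": np.arange(start, start + len(allele_pairs)),
            "genetic_pos": 0.0,
            "allele1": [p[0] for p in allele_pairs],
            "allele2": [p[1] for p in allele_pairs],
            "ancestral": UNKNOWN}))

    def test_swapped_alleles_recode(self):
        p1 = self._panel([("A", "C")])
        p2 = self._panel([("C", "A")])
        m1 = GenotypeMatrix(["a"], np.array([2], np.int8),
                            np.array([[2]], np.int8))
        m2 = GenotypeMatrix(["b"], np.array([2], np.int8),
                            np.array([[2]], np.int8))
        panel, matrix, report = merge_datasets([(p1, m1), (p2, m2)])
        assert matrix.calls[0, 0] == 2 and matrix.calls[1, 0] == 0
        assert report.n_kept == 1

    def test_triallelic_dropped_and_counted(self):
        p1 = self._panel([("A", "C")])
        p2 = self._panel([("A", "G")])
        m = GenotypeMatrix(["a"], np.array([2], np.int8),
                           np.array([[0]], np.int8))
        m2 = GenotypeMatrix(["b"], np.array([2], np.int8),
                            np.array([[0]], np.int8))
        _, _, report = merge_datasets([(p1, m), (p2, m2)])
        assert report.n_kept == 0
        assert report.n_triallelic_dropped == 1

    def test_ambiguous_strand_needs_no_flip_to_survive(self):
        p1 = self._panel([("A", "T")])
        p2 = self._panel([("C", "G")])
        m = GenotypeMatrix(["a"], np.array([2], np.int8),
                           np.array([[0]], np.int8))
        m2 = GenotypeMatrix(["b"], np.array([2], np.int8),
                            np.array([[0]], np.int8))
        _, _, report = merge_datasets([(p1, m), (p2, m2)])
        assert report.n_ambiguous_dropped == 1
        assert report.n_kept == 0

    def test_strand_flip_at_unambiguous_transversion(self):
        p1 = self._panel([("A", "C")])
        p2 = self._panel([("T", "G")])  # complement of A/C
        m1 = GenotypeMatrix(["a"], np.array([2], np.int8),
                            np.array([[1]], np.int8))
        m2 = GenotypeMatrix(["b"], np.array([2], np.int8),
                            np.array([[2]], np.int8))
        panel, matrix, report = merge_datasets([(p1, m1), (p2, m2)])
        assert report.n_kept == 1
        assert matrix.calls[1, 0] == 2  # flip without swap keeps coding

    def test_randomized_merge_matches_per_site_oracle(self):
        rng = np.random.default_rng(9)
        bases = "ACGT"
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pairs1, pairs2 = [], []
        for _ in range(500):
            a1, a2 = rng.choice(list(bases), 2, replace=False)
            r = rng.random()
            if r < 0.4:
                b = (a1, a2)
            elif r < 0.6:
                b = (a2, a1)
            elif r < 0.8:
                b = (comp[a1], comp[a2])
            else:
                cands = [x for x in bases if x not in (a1, a2)]
                b = (a1, rng.choice(cands))
            pairs1.append((a1, a2))
            pairs2.append(b)
        p1, p2 = self._panel(pairs1), self._panel(pairs2)
        m1 = GenotypeMatrix(["a"], np.array([2], np.int8),
                            rng.integers(0, 3, (1, 500)).astype(np.int8))
        m2 = GenotypeMatrix(["b"], np.array([2], np.int8),
                            rng.integers(0, 3, (1, 500)).astype(np.int8))
        panel, matrix, report = merge_datasets([(p1, m1), (p2, m2)])

        # independent per-site reconciliation oracle
        kept_oracle = {}
        for i, ((a1, a2), (b1, b2)) in enumerate(zip(pairs1, pairs2)):
            c = int(m2.calls[0, i])
            ambiguous = {a1, a2} in ({"A", "T"}, {"C", "G"}) or \
                {b1, b2} in ({"A", "T"}, {"C", "G"})
            transversions = not is_transition(a1, a2) \
                and not is_transition(b1, b2)
            if (b1, b2) == (a1, a2):
                kept_oracle[i + 1] = c
            elif (b1, b2) == (a2, a1):
                kept_oracle[i + 1] = 2 - c
            elif ambiguous or not transversions:
                continue  # flips attempted only at unambiguous transversions
            elif (comp[b1], comp[b2]) == (a1, a2):
                kept_oracle[i + 1] = c
            elif (comp[b1], comp[b2]) == (a2, a1):
                kept_oracle[i + 1] = 2 - c
        got = dict(zip(panel.sites["pos"], matrix.calls[1]))
        assert got == kept_oracle

    def test_merge_is_idempotent_under_self_intersection(self, random_dataset):
        panel, matrix, meta = random_dataset
        p1, m1, rep = merge_datasets([(panel, matrix)])
        assert rep.n_kept == panel.n_sites
        np.testing.assert_array_equal(m1.calls, matrix.calls)


class TestPolarize:
    def test_ancestral_allele2_flips_counts(self, tiny_panel):
        sites = tiny_panel.sites.copy()
        sites.loc[0, "ancestral"] = "C"
        panel = SnpPanel(sites)
        m = GenotypeMatrix(["a", "b"], np.array([2, 1], np.int8),
                           np.array([[2, 1, 0, MISSING, 2],
                                     [1, 0, 1, 1, MISSING]], np.int8))
        p2, m2 = polarize(panel, m, "panel")
        assert m2.calls[0, 0] == 0 and m2.calls[1, 0] == 0
        assert m2.calls[0, 1] == 1  # ancestral = allele1: unchanged
        assert m2.calls[0, 3] == MISSING
        assert (p2.sites["ancestral"] == p2.sites["allele1"]).all()

    def test_outgroup_individual_defines_ancestral(self, tiny_panel):
        m = GenotypeMatrix(["chimp", "x"], np.array([2, 2], np.int8),
                           np.array([[0, 2, 1, 0, MISSING],
                                     [1, 1, 1, 1, 1]], np.int8))
        p2, m2 = polarize(tiny_panel, m, "chimp")
        # het and missing outgroup sites dropped
        assert p2.n_sites == 3
        assert list(m2.calls[1]) == [1, 1, 1]
        assert p2.sites["ancestral"].iloc[1] == "C"

    def test_no_ancestral_information_errors(self, tiny_panel):
        sites = tiny_panel.sites.copy()
        sites["ancestral"] = UNKNOWN
        m = GenotypeMatrix(["a"], np.array([2], np.int8),
                           np.zeros((1, 5), np.int8))
        with pytest.raises(InvariantError):
            polarize(SnpPanel(sites), m, "panel")


class TestGroupFrequencies:
    def test_single_pseudohaploid_and_missing_handling(self):
        m = GenotypeMatrix(["a", "b", "c"], np.array([1, 2, 2], np.int8),
                           np.array([[1, 0], [2, MISSING], [MISSING, 2]],
                                    np.int8))
        meta = make_meta([{"id": "a", "group": "P", "sex": "UNKNOWN"},
                          {"id": "b", "group": "Q", "sex": "UNKNOWN"},
                          {"id": "c", "group": "Q", "sex": "UNKNOWN"}])
        gf = group_frequencies(m, meta)
        p, q = gf.index_of("P"), gf.index_of("Q")
        assert gf.freq[p, 0] == 1.0 and gf.totals[p, 0] == 1
        assert gf.freq[q, 0] == 1.0 and gf.totals[q, 0] == 2
        assert gf.freq[q, 1] == 1.0 and gf.totals[q, 1] == 2

    def test_matches_direct_count_oracle(self, random_dataset):
        panel, matrix, meta = random_dataset
        gf = group_frequencies(matrix, meta)
        for g in gf.groups:
            gi = gf.index_of(g)
            members = [i for i, ind in enumerate(matrix.individuals)
                       if dict(zip(meta["id"], meta["group"]))[ind] == g]
            for s in range(matrix.n_sites):
                num = den = 0
                for i in members:
                    c = matrix.calls[i, s]
                    if c != MISSING:
                        num += int(c)
                        den += int(matrix.ploidy[i])
                if den:
                    assert gf.freq[gi, s] == pytest.approx(num / den)
                    assert gf.totals[gi, s] == den
                else:
                    assert np.isnan(gf.freq[gi, s])

    def test_empty_grouping_rejected(self, random_dataset):
        panel, matrix, meta = random_dataset
        with pytest.raises(InvariantError):
            group_frequencies(matrix, meta, {})
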