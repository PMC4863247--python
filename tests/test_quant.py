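import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_dataset
from crossomics import quant
from crossomics.quant import (
    ONLY_T24,
    ONLY_T24M,
    QuantParseError,
    SignalAnnotation,
    core_proteome,
    detection_filter,
    enrichment_report,
    exclude_contaminants,
    impute_missing,
    ppm_normalize,
    read_quant_table,
    write_quant_table,
)


class TestReadWrite:
    def test_round_trip(self, tiny_dataset, tmp_path):
        path = tmp_path / "q.tsv"
        write_quant_table(tiny_dataset, path, header_comment="test")
        back = read_quant_table(path, "CE")
        pd.testing.assert_frame_equal(back.intensities, tiny_dataset.intensities)
        pd.testing.assert_frame_equal(back.peptide_counts, tiny_dataset.peptide_counts)
        assert back.intensities.shape == (3, 10)

    def test_intensity_without_peptides_rejected(self, tiny_dataset, tmp_path):
        tiny_dataset.peptide_counts.iloc[0, 0] = 0  # intensity stays > 0
        path = tmp_path / "bad.tsv"
        out = pd.DataFrame({"accession": tiny_dataset.accessions})
        for s in tiny_dataset.samples:
            out[f"area_{s}"] = tiny_dataset.intensities[s].to_numpy()
            out[f"pep_{s}"] = tiny_dataset.peptide_counts[s].to_numpy()
        out.to_csv(path, sep="\t", index=False)
        with pytest.raises(QuantParseError, match="peptide_count == 0"):
            read_quant_table(path, "CE")

    def test_duplicate_accession_rejected(self, tiny_dataset, tmp_path):
        path = tmp_path / "dup.tsv"
        write_quant_table(tiny_dataset, path)
        lines = path.read_text().splitlines()
        lines.append(lines[1])  # repeat first data row
        path.write_text("\n".join(lines))
        with pytest.raises(QuantParseError, match="duplicate"):
            read_quant_table(path, "CE")

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("protein\tarea_T24_1\tpep_T24_1\nX\t1\t2\n")
        with pytest.raises(QuantParseError, match="accession"):
            read_quant_table(path, "CE")

    def test_generator_file_has_ten_samples(self, default_sim, tmp_path):
        cfg, datasets, _ = default_sim
        path = tmp_path / "cm.tsv"
        write_quant_table(datasets["CM"], path)
        back = read_quant_table(path, "CM")
        assert len(back.samples) == 10
        assert len(back.accessions) == cfg.n_proteins["CM"] + cfg.n_contaminants


class TestContaminants:
    def test_empty_list_is_identity(self, tiny_dataset):
        out = exclude_contaminants(tiny_dataset, set())
        pd.testing.assert_frame_equal(out.intensities, tiny_dataset.intensities)

    def test_all_accessions_removed(self, tiny_dataset):
        out = exclude_contaminants(tiny_dataset, set(tiny_dataset.accessions))
        assert out.accessions == []

    def test_twelve_of_thousand(self):
        rng = np.random.default_rng(1)
        d = make_dataset(rng.lognormal(10, 0.3, (1000, 10)), np.full((1000, 10), 2))
        out = exclude_contaminants(d, set(d.accessions[:12]))
        assert len(out.accessions) == 988
        assert out.accessions == d.accessions[12:]  # order preserved


class TestPpmNormalize:
    def test_single_protein_gets_full_scale(self):
        # a lone protein carries the entire sample signal regardless of area
        d = make_dataset([[7.0] * 10], [[2] * 10])
        n = ppm_normalize(d)
        assert np.allclose(n.ppm.to_numpy(), 1e6)

    def test_equal_areas_split_evenly(self):
        d = make_dataset([[4.0] * 10, [4.0] * 10], np.full((2, 10), 2))
        n = ppm_normalize(d)
        assert np.allclose(n.ppm.to_numpy(), 5e5)

    def test_one_three_split(self):
        d = make_dataset([[1.0] * 10, [3.0] * 10], np.full((2, 10), 2))
        n = ppm_normalize(d)
        assert np.allclose(n.ppm.iloc[0], 2.5e5)
        assert np.allclose(n.ppm.iloc[1], 7.5e5)

    def test_sample_sums_hit_scale(self, default_sim):
        _, datasets, _ = default_sim
        n = ppm_normalize(datasets["CE"])
        assert np.allclose(n.ppm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_area_names_sample(self):
        d = make_dataset(np.zeros((2, 10)), np.zeros((2, 10), dtype=int))
        with pytest.raises(ValueError, match="T24_1"):
            ppm_normalize(d)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_per_sample(self, c):
        rng = np.random.default_rng(3)
        intens = rng.lognormal(8, 0.5, (5, 10))
        d = make_dataset(intens, np.full((5, 10), 2))
        scaled = intens.copy()
        scaled[:, 2] *= c
        d2 = make_dataset(scaled, np.full((5, 10), 2))
        a, b = ppm_normalize(d).ppm.to_numpy(), ppm_normalize(d2).ppm.to_numpy()
        assert np.allclose(a, b, rtol=1e-9)


class TestDetectionFilter:
    @staticmethod
    def _peps(t24, t24m):
        row = [2 if k else 0 for k in t24] + [2 if k else 0 for k in t24m]
        intens = [[10.0 if p else 0.0 for p in row]]
        return make_dataset(intens, [row])

    def test_exclusive_detection_one_line(self):
        d = self._peps([1, 1, 1, 1, 1], [0, 0, 0, 0, 0])
        m = detection_filter(d)
        assert m.retained.iloc[0]
        assert m.exclusivity.iloc[0] == ONLY_T24

        d = self._peps([0, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        m = detection_filter(d)
        assert m.exclusivity.iloc[0] == ONLY_T24M

    def test_below_threshold_in_both_groups(self):
        m = detection_filter(self._peps([1, 1, 0, 0, 0], [1, 1, 0, 0, 0]))
        assert not m.retained.iloc[0]

    def test_one_group_passing_retains_without_exclusivity(self):
        m = detection_filter(self._peps([1, 1, 1, 0, 0], [1, 0, 0, 0, 0]))
        assert m.retained.iloc[0]
        assert m.exclusivity.iloc[0] == "none"

    def test_depends_only_on_peptide_counts(self):
        peps = np.array([[3, 3, 3, 0, 0, 0, 0, 0, 0, 0]])
        a = make_dataset(np.where(peps > 0, 5.0, 0.0), peps)
        b = make_dataset(np.where(peps > 0, 500.0, 0.0), peps)
        ma, mb = detection_filter(a), detection_filter(b)
        pd.testing.assert_frame_equal(ma.detected, mb.detected)
        pd.testing.assert_series_equal(ma.retained, mb.retained)

    def test_min_replicates_larger_than_group_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            detection_filter(tiny_dataset, min_replicates=6)


class TestImputeMissing:
    def test_identity_when_nothing_missing(self, tiny_dataset):
        n = ppm_normalize(tiny_dataset)
        m = detection_filter(tiny_dataset)
        out = impute_missing(n, m)
        pd.testing.assert_frame_equal(out.ppm, n.ppm)

    def test_flagged_cell_gets_group_mean_after_zero_fill(self):
        # T24 ppm values 100,200,300,(undetected),(flagged) -> flag = mean(100,200,300,0)
        intens = np.array([[100.0, 200, 300, 0, 50, 10, 10, 10, 10, 10],
                          [900.0, 800, 700, 1000, 950, 990, 990, 990, 990, 990]])
        peps = np.array([[2, 2, 2, 0, 2, 2, 2, 2, 2, 2],
                        [2] * 10])
        d = make_dataset(intens, peps)
        n = quant.NormalizedDataset(  # use raw values as 'ppm' for arithmetic clarity
            fraction_label="CE", ppm=d.intensities.copy(),
            total_area=d.intensities.sum(), groups=d.groups,
            replicate_index=d.replicate_index,
        )
        m = detection_filter(d)
        flags = pd.DataFrame(False, index=n.ppm.index, columns=n.ppm.columns)
        flags.iloc[0, 4] = True
        out = impute_missing(n, m, flags)
        assert out.ppm.iloc[0, 3] == 0.0
        assert out.ppm.iloc[0, 4] == pytest.approx(150.0)
        assert out.ppm.iloc[0, 0] == 100.0

    def test_fully_undetected_protein_becomes_zero_row(self):
        intens = np.vstack([np.zeros(10), np.full(10, 5.0)])
        peps = np.vstack([np.zeros(10, int), np.full(10, 2)])
        d = make_dataset(intens, peps)
        out = impute_missing(ppm_normalize(d), detection_filter(d))
        assert (out.ppm.iloc[0] == 0).all()

    def test_all_flagged_group_is_an_error(self, tiny_dataset):
        n = ppm_normalize(tiny_dataset)
        m = detection_filter(tiny_dataset)
        flags = pd.DataFrame(False, index=n.ppm.index, columns=n.ppm.columns)
        flags.loc[flags.index[0], [c for c in flags.columns if c.startswith("T24_")]] = True
        with pytest.raises(ValueError, match="flagged"):
            impute_missing(n, m, flags)


class TestCoreProteome:
    def test_identical_sets(self):
        s = {"a", "b", "c", "d", "e"}
        regions = core_proteome({"CE": s, "ERGolgi": s, "CM": s})
        assert regions[("CE", "CM", "ERGolgi")] == 5
        assert sum(v for k, v in regions.items() if len(k) < 3) == 0

    def test_disjoint_sets(self):
        regions = core_proteome({"CE": {1, 2}, "ERGolgi": {3, 4, 5}, "CM": {6, 7, 8, 9}})
        assert regions[("CE",)] == 2
        assert regions[("ERGolgi",)] == 3
        assert regions[("CM",)] == 4
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    def test_chained_overlap_enumeration(self):
        regions = core_proteome({"CE": {1, 2, 3}, "ERGolgi": {2, 3, 4}, "CM": {3, 4, 5}})
        assert regions[("CE", "CM", "ERGolgi")] == 1
        assert regions[("CE", "ERGolgi")] == 1
        assert regions[("CM", "ERGolgi")] == 1
        assert regions[("CE", "CM")] == 0
        # element-by-element: 1 only in CE, 5 only in CM, nothing only in ERGolgi
        assert regions[("CE",)] == 1
        assert regions[("ERGolgi",)] == 0
        assert regions[("CM",)] == 1
        assert sum(regions.values()) == 5

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        sets = {f: set(rng.choice(100, 40, replace=False)) for f in ("CE", "ERGolgi", "CM")}
        regions = core_proteome(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_relabeling_invariance(self):
        sets = {"CE": {1, 2, 3}, "ERGolgi": {2, 3, 4}, "CM": {3, 4, 5}}
        r1 = core_proteome(sets)
        swapped = {"CE": sets["CM"], "CM": sets["CE"], "ERGolgi": sets["ERGolgi"]}
        r2 = core_proteome(swapped)
        relabel = {"CE": "CM", "CM": "CE", "ERGolgi": "ERGolgi"}
        for k, v in r1.items():
            assert r2[tuple(sorted(relabel[x] for x in k))] == v

    def test_single_fraction_rejected(self):
        with pytest.raises(ValueError):
            core_proteome({"CE": {1}})


class TestEnrichmentReport:
    def _setup(self, flags):
        rng = np.random.default_rng(7)
        d = make_dataset(rng.lognormal(8, 0.4, (len(flags), 10)),
                         np.full((len(flags), 10), 2))
        n = ppm_normalize(d)
        m = detection_filter(d)
        ann = SignalAnnotation(dict(zip(d.accessions, flags)))
        return n, m, ann

    def test_all_secreted(self):
        n, m, ann = self._setup([True] * 4)
        rep = enrichment_report(n, m, ann)
        assert rep.pct_signal_proteins == 100.0
        assert rep.pct_signal_intensity == pytest.approx(100.0)

    def test_none_secreted(self):
        n, m, ann = self._setup([False] * 4)
        rep = enrichment_report(n, m, ann)
        assert rep.pct_signal_proteins == 0.0
        assert rep.pct_signal_intensity == 0.0

    def test_monotone_in_signal_count(self):
        pcts = []
        for k in range(5):
            n, m, ann = self._setup([True] * k + [False] * (4 - k))
            pcts.append(enrichment_report(n, m, ann).pct_signal_proteins)
        assert pcts == sorted(pcts)

    def test_empty_retained_is_error(self):
        d = make_dataset([[1.0] * 10, [1.0] * 10], np.ones((2, 10), int))
        n, m = ppm_normalize(d), detection_filter(d)  # 1 peptide -> nothing retained
        with pytest.raises(ValueError):
            enrichment_report(n, m, SignalAnnotation({}))

    def test_marker_ratios_across_fractions(self):
        d_cm = make_dataset([[8.0] * 10, [2.0] * 10], np.full((2, 10), 2), fraction="CM")
        d_ce = make_dataset([[2.0] * 10, [8.0] * 10], np.full((2, 10), 2), fraction="CE")
        n_cm, n_ce = ppm_normalize(d_cm), ppm_normalize(d_ce)
        m = detection_filter(d_cm)
        marker = d_cm.accessions[0]
        rep = enrichment_report(
            n_cm, m, SignalAnnotation({}), markers={marker: "CM"},
            other_fractions={"CE": n_ce, "CM": n_cm},
        )
        # 8/10 of CM signal vs 2/10 of CE signal -> 4-fold enrichment
        assert rep.marker_ratios[marker]["CE"] == pytest.approx(4.0)

    def test_missing_annotation_defaults_negative(self, default_sim):
        _, datasets, _ = default_sim
        d = datasets["CM"]
        n, m = ppm_normalize(d), detection_filter(d)
        rep = enrichment_report(n, m, SignalAnnotation({}))
        assert rep.pct_signal_proteins == 0.0
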