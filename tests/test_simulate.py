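"""Synthetic transcriptome and tag-library generator."""


import numpy as np
import pytest

from tagdge.mapping import TagCountTable
from tagdge.reference import extract_reference_tags
from tagdge.simulate import (
    LibrarySpec,
    SimulationTruth,
    SyntheticTranscript,
    generate_transcriptome,
    make_truth,
    simulate_tag_library,
    usable_tag_sites,
)

import pandas as pd


def _single_gene_truth(gene_id="g1", conditions=("control", "t")):
    weights = pd.DataFrame(
        {c: [1.0] for c in conditions}, index=pd.Index([gene_id], name="gene_id")
    )
    direction = pd.DataFrame(
        "null", index=weights.index, columns=[c for c in conditions if c != "control"]
    )
    return SimulationTruth(weights, direction, "control")


class TestGenerateTranscriptome:
    def test_zero_density_suppresses_motif(self):
        transcripts = generate_transcriptome(50, mean_length=100, catg_density=0, seed=1)
        for t in transcripts:
            assert "CATG" not in t.sequence

    def test_density_yields_sites_in_most_transcripts(self):
        transcripts = generate_transcriptome(500, mean_length=789, catg_density=10, seed=7)
        with_site = sum("CATG" in t.sequence for t in transcripts)
        assert with_site / len(transcripts) >= 0.90

    def test_deterministic_given_seed(self):
        a = generate_transcriptome(30, 200, 5.0, seed=7)
        b = generate_transcriptome(30, 200, 5.0, seed=7)
        assert [(t.gene_id, t.sequence) for t in a] == [
            (t.gene_id, t.sequence) for t in b
        ]

    def test_length_floor_and_mean(self):
        transcripts = generate_transcriptome(2000, mean_length=300, catg_density=1, seed=3)
        lengths = np.array([t.length for t in transcripts])
        assert lengths.min() >= 60
        # geometric lengths: sample mean within 5 sd of the target
        assert abs(lengths.mean() - 300) < 5 * lengths.std() / np.sqrt(len(lengths))

    @pytest.mark.parametrize("kwargs", [dict(n_genes=0), dict(mean_length=59)])
    def test_parameter_errors(self, kwargs):
        defaults = dict(n_genes=5, mean_length=100, catg_density=1.0, seed=0)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            generate_transcriptome(**defaults)


class TestSimulateTagLibrary:
    def test_single_gene_error_free(self):
        seq = "A" * 30 + "CATG" + "GTCAGTCAGTCAGTCAG" + "A" * 30
        t = SyntheticTranscript("g1", seq)
        table, stats = simulate_tag_library(
            [t], _single_gene_truth(), LibrarySpec("t", depth=10, error_rate=0, seed=3)
        )
        expected = seq[30:51]
        assert table.entries == {expected: 10}
        assert table.library_size == 10
        assert stats.true_counts == {"g1": 10}

    def test_three_prime_most_site_chosen(self):
        # two sites; the 3'-most has a full 17-nt extension
        seq = "CATG" + "A" * 17 + "T" * 10 + "CATG" + "C" * 17 + "G" * 5
        t = SyntheticTranscript("g1", seq + "A" * 10)
        table, _ = simulate_tag_library(
            [t], _single_gene_truth(), LibrarySpec("t", depth=5, error_rate=0, seed=1)
        )
        (tag,) = table.entries
        assert tag == "CATG" + "C" * 17

    def test_site_too_close_to_end_skipped(self):
        # 3'-most CATG has only 10 nt downstream -> falls back to earlier site
        seq = "T" * 30 + "CATG" + "G" * 17 + "AA" + "CATG" + "C" * 10
        t = SyntheticTranscript("g1", seq)
        assert usable_tag_sites(seq) == [30]
        table, _ = simulate_tag_library(
            [t], _single_gene_truth(), LibrarySpec("t", depth=4, error_rate=0, seed=1)
        )
        assert set(table.entries) == {"CATG" + "G" * 17}

    def test_gene_without_site_unobservable(self):
        t = SyntheticTranscript("g1", "A" * 80)
        with pytest.raises(ValueError):
            simulate_tag_library(
                [t], _single_gene_truth(), LibrarySpec("t", 5, 0.0, 1)
            )

    def test_abundance_ratio_recovered(self):
        seqs = [
            SyntheticTranscript("g1", "A" * 30 + "CATG" + "GTCAGTCAGTCAGTCAG" + "A" * 30),
            SyntheticTranscript("g2", "T" * 30 + "CATG" + "ACGTACGTACGTACGTA" + "T" * 30),
        ]
        weights = pd.DataFrame(
            {"control": [1.0, 3.0], "t": [1.0, 3.0]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        truth = SimulationTruth(
            weights, pd.DataFrame("null", index=weights.index, columns=["t"]), "control"
        )
        depth = 100_000
        table, stats = simulate_tag_library(
            seqs, truth, LibrarySpec("t", depth=depth, error_rate=0, seed=5)
        )
        c2 = stats.true_counts["g2"]
        se = np.sqrt(depth * 0.75 * 0.25)
        assert abs(c2 - 0.75 * depth) < 3 * se

    def test_error_rate_matches_closed_form(self):
        t = SyntheticTranscript(
            "g1", "A" * 30 + "CATG" + "GTCAGTCAGTCAGTCAG" + "A" * 30
        )
        depth = 40_000
        table, _ = simulate_tag_library(
            [t],
            _single_gene_truth(),
            LibrarySpec("t", depth=depth, error_rate=0.01, seed=9),
            keep_dirty=True,
        )
        source = t.sequence[30:51]
        n_err = sum(c for tag, c in table.entries.items() if tag != source)
        p_err = 1 - 0.99**21
        se = np.sqrt(depth * p_err * (1 - p_err))
        assert abs(n_err - depth * p_err) < 4 * se
        assert table.library_size == depth  # raw table keeps every emitted tag

    def test_depth_exact_and_deterministic(self, small_transcriptome):
        truth = make_truth([t.gene_id for t in small_transcriptome], seed=2)
        spec = LibrarySpec("12h", depth=5000, error_rate=0.02, seed=4)
        t1, s1 = simulate_tag_library(small_transcriptome, truth, spec, keep_dirty=True)
        t2, s2 = simulate_tag_library(small_transcriptome, truth, spec, keep_dirty=True)
        assert t1.entries == t2.entries
        assert t1.n_copies == 5000
        assert s1.n_clean + s1.n_dirty == 5000

    def test_error_free_tags_all_in_reference(self, small_transcriptome):
        truth = make_truth([t.gene_id for t in small_transcriptome], seed=2)
        table, _ = simulate_tag_library(
            small_transcriptome, truth, LibrarySpec("24h", 3000, 0.0, 8)
        )
        db = extract_reference_tags(small_transcriptome)
        for tag in table.entries:
            assert db.lookup(tag), f"simulated tag {tag} missing from reference DB"


class TestMakeTruth:
    def test_novel_genes_silent_in_control(self):
        truth = make_truth(
            [f"g{i}" for i in range(200)], frac_novel=0.05, seed=1
        )
        novel = truth.direction.apply(lambda row: (row == "novel").any(), axis=1)
        assert novel.sum() == 10
        assert (truth.baseline[novel] == 0).all()
        assert ((truth.weights.loc[novel].drop(columns="control") > 0).any(axis=1)).all()

    def test_fold_changes_applied(self):
        truth = make_truth([f"g{i}" for i in range(300)], fold_change=4.0, seed=3)
        for cond in ("12h", "24h", "48h"):
            up = truth.genes_with_direction(cond, "up")
            down = truth.genes_with_direction(cond, "down")
            fc = truth.fold_change(cond)
            assert np.allclose(fc[sorted(up)], 4.0)
            assert np.allclose(fc[sorted(down)], 0.25)

    def test_roundtrip_through_frame(self):
        truth = make_truth([f"g{i}" for i in range(50)], seed=5)
        back = SimulationTruth.from_frame(truth.to_frame(), control="control")
        pd.testing.assert_frame_equal(truth.weights, back.weights[truth.weights.columns])


class TestSpecValidation:
    def test_library_spec_bounds(self):
        with pytest.raises(ValueError):
            LibrarySpec("x", depth=0)
        with pytest.raises(ValueError):
            LibrarySpec("x", depth=10, error_rate=0.2)

    def test_transcript_invariants(self):
        with pytest.raises(ValueError):
            SyntheticTranscript("g", "ACGT" * 10)  # 40 nt < 60
        with pytest.raises(ValueError):
            SyntheticTranscript("g", "ACGN" * 20)
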