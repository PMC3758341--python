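import filecmp

import numpy as np
import pytest

from imco import (
    ProteinSequence,
    SyntheticConfig,
    ValidationError,
    annotate_im,
    estimate_conflict_rate,
    estimate_points,
    exon_points,
    generate_conflicts,
    generate_gtf,
    generate_pairs,
    generate_sequences,
    global_align,
    im_probability,
    percent_identity,
    poisson_conflict_filter,
    read_fasta,
    read_gtf,
    spearman_trend,
)
from imco.synthetic_data import ConflictModel, ExonModel, IMModel


class TestIMProbability:
    def test_zero_escape_probability(self):
        assert im_probability(0.0, 7) == 0.0

    def test_single_exon_gene(self):
        assert im_probability(0.25, 1) == 0.0

    def test_saturating_formula(self):
        assert im_probability(0.25, 5) == pytest.approx(1 - 0.75**4)

    def test_saturates_towards_one(self):
        e = np.arange(1, 60)
        p = im_probability(0.25, e)
        assert np.all(np.diff(p) > 0) and p[-1] > 0.999


class TestGeneratePairs:
    def test_reproducible_from_seed(self):
        cfg = SyntheticConfig(n_pairs=500, seed=9)
        p1, t1 = generate_pairs(cfg)
        p2, t2 = generate_pairs(cfg)
        assert p1 == p2
        assert t1.table.equals(t2.table)

    def test_identities_respect_truncation(self, default_pairs):
        pairs, _ = default_pairs
        psis = np.array([p.psi for p in pairs])
        assert psis.min() >= 30.0 and psis.max() <= 100.0

    def test_no_im_without_multiple_exons(self, default_pairs):
        pairs, _ = default_pairs
        for p in pairs:
            if p.exons_h == 1:
                assert not p.im_h
            if p.exons_m == 1:
                assert not p.im_m

    def test_comonotone_coupling(self):
        cfg = SyntheticConfig(n_pairs=20_000, seed=4,
                              im_model=IMModel(coupling=1.0))
        pairs, truth = generate_pairs(cfg)
        # with a shared uniform, both species have IM iff u < min(p_h, p_m)
        p_min = np.minimum(truth.table["p_im_h"], truth.table["p_im_m"])
        both = truth.table["im_h"] & truth.table["im_m"]
        assert np.mean(both) == pytest.approx(np.mean(p_min), abs=0.01)
        either = truth.table["im_h"] | truth.table["im_m"]
        p_max = np.maximum(truth.table["p_im_h"], truth.table["p_im_m"])
        assert np.mean(either) == pytest.approx(np.mean(p_max), abs=0.01)

    def test_vertebrate_and_fly_regimes(self):
        up = SyntheticConfig(n_pairs=8000, seed=5)
        down = SyntheticConfig(
            n_pairs=8000, seed=5,
            exon_model=ExonModel(intercept=np.log(8.0), slope=-0.012),
        )
        for cfg, sign in ((up, 1), (down, -1)):
            pairs, _ = generate_pairs(cfg)
            df = exon_points(pairs)
            df = df[df["n_pairs"] >= 5]
            t = spearman_trend(df["x"], df["mean_exons_h"])
            assert sign * t.rho > 0 and t.p_value < 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_pairs=0)
        with pytest.raises(ValidationError):
            IMModel(q_h=1.5)


class TestGenerateSequences:
    def test_identical_at_full_identity(self, tmp_path):
        cfg = SyntheticConfig(n_pairs=5, seed=1)
        pairs, _ = generate_pairs(cfg)
        pairs = [p.__class__(**{**p.__dict__, "psi": 100.0}) for p in pairs]
        generate_sequences(pairs, cfg, tmp_path / "h.fa", tmp_path / "m.fa")
        h = read_fasta(tmp_path / "h.fa")
        m = read_fasta(tmp_path / "m.fa")
        for a, b in zip(h, m):
            assert a.residues == b.residues

    def test_substitution_count_construction(self, tmp_path):
        cfg = SyntheticConfig(n_pairs=30, seed=2)
        pairs, _ = generate_pairs(cfg)
        lengths = generate_sequences(pairs, cfg, tmp_path / "h.fa", tmp_path / "m.fa")
        h = {s.seq_id: s for s in read_fasta(tmp_path / "h.fa")}
        m = {s.seq_id: s for s in read_fasta(tmp_path / "m.fa")}
        for pair, L in zip(pairs, lengths):
            a, b = h[pair.human_gene], m[pair.other_gene]
            assert len(a.residues) == len(b.residues) == L
            n_diff = sum(x != y for x, y in zip(a.residues, b.residues))
            assert n_diff == round(L * (1 - pair.psi / 100))

    def test_realized_identity_matches_target(self, tmp_path):
        cfg = SyntheticConfig(n_pairs=200, seed=3)
        pairs, _ = generate_pairs(cfg)
        generate_sequences(pairs, cfg, tmp_path / "h.fa", tmp_path / "m.fa")
        h = {s.seq_id: s for s in read_fasta(tmp_path / "h.fa")}
        m = {s.seq_id: s for s in read_fasta(tmp_path / "m.fa")}
        within = 0
        for pair in pairs:
            psi = percent_identity(
                global_align(h[pair.human_gene], m[pair.other_gene])
            )
            within += abs(psi - pair.psi) <= 0.5
        assert within >= 0.99 * len(pairs)

    def test_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(n_pairs=50, seed=6)
        pairs, _ = generate_pairs(cfg)
        for run in ("a", "b"):
            d = tmp_path / run
            d.mkdir()
            generate_sequences(pairs, cfg, d / "h.fa", d / "m.fa")
            generate_gtf(pairs, cfg, d / "h.gtf", d / "m.gtf")
        for name in ("h.fa", "m.fa", "h.gtf", "m.gtf"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False)


@pytest.fixture(scope="module")
def annotated(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("gtf")
    cfg = SyntheticConfig(n_pairs=120, seed=8)
    pairs, _ = generate_pairs(cfg)
    generate_gtf(pairs, cfg, tmp / "h.gtf", tmp / "m.gtf")
    return pairs, read_gtf(tmp / "h.gtf"), read_gtf(tmp / "m.gtf")


class TestGenerateGtf:
    def test_isoform_counts_match_im_flags(self, annotated):
        pairs, genes_h, _ = annotated
        by_id = {g.gene_id: g for g in genes_h}
        for p in pairs:
            n_tx = len(by_id[p.human_gene].transcripts)
            assert (n_tx > 1) == p.im_h

    def test_roundtrip_recovers_exons_longest(self, annotated):
        pairs, genes_h, genes_m = annotated
        im_h = {g.gene_id: annotate_im(g) for g in genes_h}
        im_m = {g.gene_id: annotate_im(g) for g in genes_m}
        for p in pairs:
            assert im_h[p.human_gene].exons_longest == p.exons_h
            assert im_m[p.other_gene].exons_longest == p.exons_m
            assert im_h[p.human_gene].has_im == p.im_h
            assert im_m[p.other_gene].has_im == p.im_m


class TestGenerateConflicts:
    def test_zero_rate_all_zero(self):
        cfg = SyntheticConfig(
            n_pairs=200, seed=1,
            conflict_model=ConflictModel(rate=0.0, outlier_fraction=0.0),
        )
        sample = generate_conflicts(cfg)
        assert all(r.n_conflicts == 0 for r in sample.records)

    def test_no_outliers_single_regime(self):
        cfg = SyntheticConfig(
            n_pairs=500, seed=2,
            conflict_model=ConflictModel(rate=0.001, outlier_fraction=0.0),
        )
        sample = generate_conflicts(cfg)
        assert not sample.is_outlier.any()

    def test_filter_separates_outliers(self):
        # rate 1e-3, 5% outliers at 20x: the Poisson test should catch most
        # outliers while keeping the baseline false-positive rate near alpha
        cfg = SyntheticConfig(
            n_pairs=2000, seed=12,
            conflict_model=ConflictModel(rate=0.001, outlier_fraction=0.05,
                                         outlier_multiplier=20.0),
        )
        sample = generate_conflicts(cfg)
        rate = estimate_conflict_rate(sample.records)
        _, excluded = poisson_conflict_filter(sample.records, rate, alpha=0.05)
        excluded = set(excluded)
        outlier_ids = {r.gene_id for r, o in zip(sample.records, sample.is_outlier) if o}
        baseline_ids = {r.gene_id for r in sample.records} - outlier_ids
        caught = len(outlier_ids & excluded) / len(outlier_ids)
        false_pos = len(baseline_ids & excluded) / len(baseline_ids)
        assert caught >= 0.80
        assert false_pos <= 0.07
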