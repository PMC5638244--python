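"""RSCU, relative adaptiveness, CAI, Nc, and correspondence analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genomesurvey.codon_usage import (
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    axis_cai_correlation,
    cai,
    codon_counts,
    correspondence_axes,
    enc,
    relative_adaptiveness,
    rscu,
)
from genomesurvey.synthetic_data import OPTIMAL_CODONS, simulate_coding_sequences


def _cds(codons: list[str]) -> str:
    return "ATG" + "".join(codons) + "TAA"


class TestRscu:
    def test_uniform_usage_is_unity(self):
        # one copy of every sense codon -> every family perfectly uniform
        seq = _cds([c for c in SENSE_CODONS if c != "ATG"])
        values = rscu(seq)
        for fam in SYNONYMOUS_FAMILIES.values():
            for codon in fam:
                assert values[codon] == pytest.approx(1.0)

    def test_two_fold_family_counts(self):
        seq = _cds(["TTC", "TTC", "TTC", "TTT"])
        values = rscu(seq)
        assert values["TTC"] == pytest.approx(1.5)
        assert values["TTT"] == pytest.approx(0.5)

    def test_single_codon_families(self):
        seq = _cds(["TGG"])
        values = rscu(seq)
        assert values["TGG"] == pytest.approx(1.0)
        assert values["ATG"] == pytest.approx(1.0)  # start codon counts

    def test_unused_family_is_zero(self):
        seq = _cds(["TTC"])
        assert rscu(seq)["GGA"] == 0.0

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            rscu("ATGTAATTTTAA")

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError):
            rscu("ATGTT")


class TestRelativeAdaptiveness:
    def test_family_ratio(self):
        ref = [_cds(["TTC"] * 30 + ["TTT"] * 10)]
        w = relative_adaptiveness(ref)
        assert w["TTC"] == pytest.approx(1.0)
        assert w["TTT"] == pytest.approx(1 / 3)

    def test_top_codon_always_unity(self):
        ref = list(simulate_coding_sequences(5, 0.7, seed=1, n_codons=200).values())
        w = relative_adaptiveness(ref)
        for fam in SYNONYMOUS_FAMILIES.values():
            assert max(w[c] for c in fam) == pytest.approx(1.0)

    def test_absent_codon_guard(self):
        ref = [_cds(["TTC"] * 20)]
        w = relative_adaptiveness(ref)
        assert w["TTT"] == pytest.approx(0.5 / 20)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_adaptiveness([])


class TestCai:
    def test_unity_when_all_weights_unity(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        assert cai(_cds(["TTC", "GGA", "CAA"]), w) == pytest.approx(1.0)

    def test_hand_geometric_mean(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        w["TTC"] = 1.0
        w["GGA"] = 1.0
        w["CAA"] = 0.25
        w["AAA"] = 0.25
        value = cai(_cds(["TTC", "GGA", "CAA", "AAA"]), w)
        assert value == pytest.approx(0.5)

    def test_excludes_met_and_trp(self):
        w = dict.fromkeys(SENSE_CODONS, 0.5)
        with_singletons = cai(_cds(["TTC", "TGG", "ATG"]), w)
        without = cai(_cds(["TTC"]), w)
        assert with_singletons == pytest.approx(without)

    def test_only_singletons_rejected(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        with pytest.raises(ValueError):
            cai("ATGTGGTAA", w)  # Met + Trp only

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        codons = ["TTC", "TTT", "GGA", "GGC", "CAA"] * 4
        w = {c: float(v) for c, v in zip(SENSE_CODONS, rng.uniform(0.1, 1, len(SENSE_CODONS)))}
        base = cai(_cds(codons), w)
        for _ in range(3):
            rng.shuffle(codons)
            assert cai(_cds(codons), w) == pytest.approx(base)

    def test_max_bias_genes_score_unity_under_matching_reference(self):
        genes = simulate_coding_sequences(5, 1.0, seed=4, n_codons=150)
        w = relative_adaptiveness(genes.values())
        for seq in genes.values():
            assert cai(seq, w) == pytest.approx(1.0)


def enc_oracle(cds: str) -> float | None:
    """Independent recomputation of Wright's statistic."""
    counts = codon_counts(cds)
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for fam in SYNONYMOUS_FAMILIES.values():
        if len(fam) == 1:
            continue
        n = sum(counts[c] for c in fam)
        if n <= 1:
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in fam)
        F = (n * sum_p2 - 1) / (n - 1)
        if F > 0:
            by_class[len(fam)].append(F)
    means = {k: sum(v) / len(v) for k, v in by_class.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(k not in means for k in (2, 3, 4, 6)):
        return None
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(max(nc, 20.0), 61.0)


class TestEnc:
    def test_maximal_bias_scores_twenty(self):
        seq = next(iter(simulate_coding_sequences(1, 1.0, seed=5, n_codons=500).values()))
        assert enc(seq) == pytest.approx(20.0)

    def test_uniform_usage_approaches_sixty_one(self):
        seq = next(iter(simulate_coding_sequences(1, 0.0, seed=6, n_codons=3000).values()))
        assert enc(seq) == pytest.approx(61.0, abs=2.0)

    def test_matches_direct_formula_oracle(self):
        genes = simulate_coding_sequences(20, np.linspace(0, 1, 20), seed=7, n_codons=300)
        for seq in genes.values():
            assert enc(seq) == pytest.approx(enc_oracle(seq))

    def test_too_short_gene_reports_absent(self):
        assert enc(_cds(["TTC"])) is None

    def test_monotone_decreasing_in_bias(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for bias in grid:
            genes = simulate_coding_sequences(10, bias, seed=8, n_codons=400)
            means.append(np.mean([enc(s) for s in genes.values()]))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestCorrespondence:
    def _rscu_frame(self, genes: dict[str, str]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            {g: rscu(s) for g, s in genes.items()}, orient="index"
        )

    def test_identical_rows_get_identical_coordinates(self):
        seq = _cds(["TTC", "GGA", "CAA"] * 5)
        other = _cds(["TTT", "GGC", "CAG"] * 5)
        frame = self._rscu_frame({"a": seq, "b": seq, "c": other})
        coords, _ = correspondence_axes(frame, 2)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_rank_one_matrix_has_single_axis(self):
        # two distinct row profiles -> centered rank 1
        frame = pd.DataFrame(
            [[4.0, 1.0], [1.0, 4.0], [4.0, 1.0]],
            index=["a", "b", "c"],
            columns=["x", "y"],
        )
        coords, shares = correspondence_axes(frame, 4)
        assert shares.size == 1
        assert shares[0] == pytest.approx(1.0)

    def test_axes_orthogonal_under_row_masses(self):
        genes = simulate_coding_sequences(12, np.linspace(0, 1, 12), seed=9, n_codons=300)
        frame = self._rscu_frame(genes)
        coords, _ = correspondence_axes(frame, 3)
        values = frame.to_numpy(dtype=float)
        keep = values.sum(axis=0) > 0
        P = values[:, keep] / values[:, keep].sum()
        r = P.sum(axis=1)
        C = coords.to_numpy()
        for i in range(C.shape[1]):
            for j in range(i + 1, C.shape[1]):
                assert abs(np.sum(r * C[:, i] * C[:, j])) < 1e-8

    def test_inertia_shares_bounded_and_sorted(self):
        genes = simulate_coding_sequences(10, 0.5, seed=10, n_codons=300)
        _, shares = correspondence_axes(self._rscu_frame(genes), 4)
        assert shares.sum() <= 1.0 + 1e-9
        assert (np.diff(shares) <= 1e-12).all()


class TestAxisCorrelation:
    def test_linear_relation_is_perfect(self):
        x = np.arange(10, dtype=float)
        assert axis_cai_correlation(x, 0.1 + 0.05 * x) == pytest.approx(1.0)

    def test_sign_flip_handled(self):
        x = np.arange(10, dtype=float)
        assert axis_cai_correlation(-x, 0.1 + 0.05 * x) == pytest.approx(1.0)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(11)
        assert axis_cai_correlation(rng.normal(size=1000), rng.uniform(size=1000)) <= 0.1

    def test_bias_gradient_axis_tracks_cai(self):
        bias = np.linspace(0, 1, 40)
        genes = simulate_coding_sequences(40, bias, seed=12, n_codons=300)
        reference = simulate_coding_sequences(5, 1.0, seed=13, n_codons=300)
        w = relative_adaptiveness(reference.values())
        cai_values = [cai(s, w) for s in genes.values()]
        frame = pd.DataFrame.from_dict(
            {g: rscu(s) for g, s in genes.items()}, orient="index"
        )
        coords, _ = correspondence_axes(frame, 4)
        best = max(
            axis_cai_correlation(coords[c], cai_values) for c in coords.columns
        )
        assert best >= 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            axis_cai_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
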