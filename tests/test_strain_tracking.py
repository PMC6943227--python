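"""Determinant SNV sets, retention, classification and new-SNV rate."""

import numpy as np
import pandas as pd
import pytest

import fmt_engraft as fe
from fmt_engraft.strain_tracking import (
    PresenceThresholds,
    classification_summary,
    cohort_retention_summary,
)


def make_snv(freqs: dict[str, list[float]], coverage: int = 20, species: str = "sp1"):
    """SNVTable from per-sample frequency lists (NaN allowed)."""
    n = len(next(iter(freqs.values())))
    idx = pd.MultiIndex.from_product([[species], range(n)], names=["species_id", "position"])
    loci = pd.DataFrame({"ref_allele": ["A"] * n, "alt_allele": ["G"] * n}, index=idx)
    cov = pd.DataFrame({s: [coverage] * n for s in freqs}, index=idx)
    freq = pd.DataFrame({s: vals for s, vals in freqs.items()}, index=idx, dtype=float)
    return fe.SNVTable(loci=loci, coverage=cov, freq=freq)


class TestCallPresence:
    @pytest.mark.parametrize(
        "coverage,freq,state",
        [
            (20, 0.5, "present"),
            (20, 0.0, "absent"),
            (3, 0.5, "unresolved"),
            (20, None, "unresolved"),
            (20, 0.15, "unresolved"),  # inside the ambiguity band
            (20, 0.20, "present"),  # present_min inclusive
            (20, 0.10, "absent"),  # absent_max inclusive
        ],
    )
    def test_states(self, coverage, freq, state):
        call = fe.call_presence(coverage, freq)
        assert call.state == state

    def test_threshold_ordering_enforced(self):
        with pytest.raises(fe.ValidationError):
            PresenceThresholds(present_min=0.05, absent_max=0.1)


class TestDeterminantSet:
    def test_clean_separation_yields_all_positions(self):
        snv = make_snv({"don": [1.0] * 30, "rec": [0.0] * 30})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1")
        assert len(dset.donor_specific) == 30
        assert len(dset.recipient_specific) == 0

    def test_identical_samples_excluded(self):
        """Autologous control: a donor identical to the baseline has no
        determinant positions and the species is excluded."""
        rng = np.random.default_rng(2)
        freqs = list(rng.choice([0.0, 0.3, 1.0], 40))
        snv = make_snv({"don": freqs, "rec": freqs})
        assert fe.build_determinant_set(snv, "don", "rec", "sp1") is None

    def test_below_floor_excluded(self):
        snv = make_snv({"don": [1.0] * 10 + [0.5] * 20, "rec": [0.0] * 10 + [0.5] * 20})
        assert fe.build_determinant_set(snv, "don", "rec", "sp1", min_positions=20) is None
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1", min_positions=10)
        assert len(dset.donor_specific) == 10

    def test_missing_species_raises(self):
        snv = make_snv({"don": [1.0] * 30, "rec": [0.0] * 30})
        with pytest.raises(fe.NotFoundError):
            fe.build_determinant_set(snv, "don", "rec", "nope")

    def test_unresolved_positions_excluded(self):
        don = [1.0] * 30
        rec = [0.0] * 25 + [float("nan")] * 5
        snv = make_snv({"don": don, "rec": rec})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1")
        assert len(dset.donor_specific) == 25


class TestRetention:
    def test_counting(self):
        don = [1.0] * 10
        rec = [0.0] * 10
        post = [1.0] * 6 + [0.0] * 4
        snv = make_snv({"don": don, "rec": rec, "post": post})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1", min_positions=10)
        point = fe.retention_fraction(dset, snv, "post")
        assert point.donor_retention == pytest.approx(0.6)
        assert point.n_evaluable == 10

    def test_post_equals_donor_gives_full_retention(self):
        don = [1.0] * 15 + [0.0] * 15
        rec = [0.0] * 15 + [1.0] * 15
        snv = make_snv({"don": don, "rec": rec, "post": don})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1")
        point = fe.retention_fraction(dset, snv, "post")
        assert point.donor_retention == pytest.approx(1.0)
        assert point.recipient_retention == pytest.approx(0.0)

    def test_unresolved_positions_drop_from_both_sides(self):
        don = [1.0] * 10
        rec = [0.0] * 10
        post = [1.0] * 4 + [0.0] * 4 + [float("nan")] * 2
        snv = make_snv({"don": don, "rec": rec, "post": post})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1", min_positions=10)
        point = fe.retention_fraction(dset, snv, "post")
        assert point.donor_retention == pytest.approx(0.5)
        assert point.n_evaluable == 8

    def test_all_unresolved_is_missing(self):
        don = [1.0] * 20
        rec = [0.0] * 20
        post = [float("nan")] * 20
        snv = make_snv({"don": don, "rec": rec, "post": post})
        dset = fe.build_determinant_set(snv, "don", "rec", "sp1")
        point = fe.retention_fraction(dset, snv, "post")
        assert point.donor_retention is None
        assert point.reason


class TestClassifyState:
    @pytest.mark.parametrize(
        "dr,rr,expected",
        [
            (0.9, 0.1, "donor_takeover"),
            (0.1, 0.9, "recipient_persistence"),
            (0.5, 0.5, "coexistence"),
            (0.1, 0.1, "indeterminate"),
            (0.8, 0.1, "donor_takeover"),  # hi boundary inclusive
            (0.2, 0.2, "coexistence"),  # lo boundary inclusive
            (0.79, 0.1, "indeterminate"),
            (0.9, 0.3, "coexistence"),  # both above lo wins over takeover
            (None, 0.5, "indeterminate"),
        ],
    )
    def test_rules(self, dr, rr, expected):
        assert fe.classify_state(dr, rr) == expected

    def test_total_over_unit_square(self):
        grid = np.linspace(0, 1, 21)
        for dr in grid:
            for rr in grid:
                assert fe.classify_state(float(dr), float(rr)) in {
                    "donor_takeover",
                    "recipient_persistence",
                    "coexistence",
                    "indeterminate",
                }

    def test_threshold_validation(self):
        with pytest.raises(fe.ValidationError):
            fe.classify_state(0.5, 0.5, hi=0.2, lo=0.8)


class TestNewSNVRate:
    def test_identical_samples_zero(self):
        vals = list(np.random.default_rng(3).choice([0.0, 1.0], 50))
        snv = make_snv({"base": vals, "post": vals})
        pooled, per_species = fe.new_snv_rate(snv, "base", "post")
        assert pooled == 0.0
        assert per_species["sp1"] == 0.0

    def test_counting(self):
        base = [0.0] * 100
        post = [1.0] * 7 + [0.0] * 93
        snv = make_snv({"base": base, "post": post})
        pooled, _ = fe.new_snv_rate(snv, "base", "post")
        assert pooled == pytest.approx(0.07)

    def test_noise_floor_on_autologous_simulation(self, small_cohort):
        """With no displacement beyond the planted baseline, new SNVs only
        arise from read error and stay below twice the error rate."""
        _, manifest, _ = small_cohort
        spec = fe.StrainSimSpec(
            n_species=2,
            positions_per_species=500,
            displacement=0.0,
            recipient_retention=1.0,
            error_rate=0.01,
            seed=5,
        )
        snv, _ = fe.simulate_snv_cohort(spec, manifest)
        pair = manifest.pairs()[0]
        pooled, _ = fe.new_snv_rate(snv, pair.baseline_sample, pair.post_samples[3])
        assert pooled <= 2 * spec.error_rate


class TestCohortSummary:
    def _series(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "pair_id",
                "subtype",
                "species_id",
                "day",
                "donor_retention",
                "recipient_retention",
                "n_evaluable",
                "classification",
            ],
        )

    def test_single_cell(self):
        s = self._series([("r1", "UC", "sp1", 3, 0.5, 0.5, 20, "coexistence")])
        out = cohort_retention_summary(s)
        assert out.iloc[0]["mean"] == pytest.approx(0.5)
        assert out.iloc[0]["n_recipients"] == 1

    def test_hand_mean_sd_across_recipients(self):
        s = self._series(
            [
                ("r1", "CD", "sp1", 3, 0.2, 0.9, 20, "coexistence"),
                ("r2", "CD", "sp1", 3, 0.4, 0.9, 20, "coexistence"),
                ("r3", "CD", "sp1", 3, 0.6, 0.9, 20, "coexistence"),
            ]
        )
        cell = cohort_retention_summary(s).iloc[0]
        assert cell["mean"] == pytest.approx(0.4)
        assert cell["sd"] == pytest.approx(0.2)

    def test_two_level_averaging(self):
        """Recipients are weighted equally regardless of species count."""
        s = self._series(
            [
                ("r1", "CD", "sp1", 3, 0.0, 0.5, 20, "indeterminate"),
                ("r1", "CD", "sp2", 3, 1.0, 0.5, 20, "coexistence"),
                ("r2", "CD", "sp1", 3, 1.0, 0.5, 20, "coexistence"),
            ]
        )
        cell = cohort_retention_summary(s).iloc[0]
        assert cell["mean"] == pytest.approx(0.75)  # pooled mean would be 2/3
        assert cell["pooled_mean"] == pytest.approx(2 / 3)

    def test_subtype_ordering_recovered_from_generator(self, small_cohort):
        """Permissive (UC-like) arms retain more donor alleles than CD-like."""
        _, manifest, _ = small_cohort
        spec = fe.StrainSimSpec(
            n_species=3,
            positions_per_species=100,
            displacement={"CD": 0.1, "UC": 0.6},
            seed=7,
        )
        snv, _ = fe.simulate_snv_cohort(spec, manifest)
        series = fe.track_cohort(snv, manifest)
        summary = cohort_retention_summary(series)
        uc = summary[(summary.subtype == "UC") & (summary.day == 3)].iloc[0]["mean"]
        cd = summary[(summary.subtype == "CD") & (summary.day == 3)].iloc[0]["mean"]
        assert uc > cd

    def test_classification_summary_fractions_sum_to_one(self):
        s = self._series(
            [
                ("r1", "CD", "sp1", 3, 0.9, 0.1, 20, "donor_takeover"),
                ("r2", "CD", "sp1", 3, 0.5, 0.5, 20, "coexistence"),
            ]
        )
        row = classification_summary(s).iloc[0]
        total = sum(row[c] for c in ("donor_takeover", "recipient_persistence", "coexistence", "indeterminate"))
        assert total == pytest.approx(1.0)
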