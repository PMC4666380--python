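"""Polymerase-error detection, rate estimation and simulations."""

import numpy as np
import pandas as pd
import pytest

from pcrdistort.bootstrap import PositionSample, bootstrap_uniformity
from pcrdistort.errors import (
    analytic_error_prob,
    attribute_errors,
    detect_anchor_errors,
    error_load,
    estimate_error_rate,
    min_hamming_to_set,
    molecule_error_rate,
    repeated_sequencing_error_prob,
    simulate_erroneous_pcr,
    simulate_stochastic_with_errors,
)
from pcrdistort.profiles import build_profile, poisson_resample
from pcrdistort.simulate import SequencingModel
from pcrdistort.templates import build_input_pool


class TestAnalyticRates:
    def test_polymerase_molecule_rate(self):
        p, per = analytic_error_prob(4e-6, 40)
        assert p == pytest.approx(1.6e-4, rel=2e-3)
        assert per == pytest.approx(6250, rel=2e-3)

    def test_zero_rate(self):
        p, per = analytic_error_prob(0.0)
        assert p == 0.0 and np.isinf(per)

    def test_small_rate_linearises(self):
        p, _ = analytic_error_prob(1e-6, 40)
        assert p == pytest.approx(40e-6, rel=1e-4)

    def test_parameterisation_consistency(self):
        """e and p_nt describe the same process: e = 1 - (1 - p_nt)^40."""
        e = molecule_error_rate(2.7e-5)
        est = estimate_error_rate(25 * e / 1.9)
        assert est.e == pytest.approx(e, rel=1e-12)
        assert est.p_nt_exact == pytest.approx(2.7e-5, rel=1e-3)


class TestHamming:
    def test_member_of_set_is_zero(self):
        assert min_hamming_to_set("A" * 40, ["A" * 40, "C" * 40]) == 0

    def test_single_substitution_is_one(self):
        assert min_hamming_to_set("C" + "A" * 39, ["A" * 40]) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            min_hamming_to_set("ACGT", ["ACGTA"])

    def test_random_sequences_are_well_separated(self, rng):
        """Null distances to 2900 random parents stay far above 1 (the
        per-pair expectation is 30 mismatches over 40 positions)."""
        parents = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(2900)]
        queries = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(50)]
        dists = [min_hamming_to_set(q, parents) for q in queries]
        assert min(dists) >= 5
        assert 14 <= np.mean(dists) <= 30


class TestAttribution:
    def _profile_with_errors(self, rng, n_inputs=300, n_errors=120):
        pool = build_input_pool(n_inputs, {"BC1-BC1": 1.0}, rng)
        seqs = [m.barcode_pair for m in pool]
        rows = [(s, int(r)) for s, r in zip(seqs, rng.poisson(1000, n_inputs))]
        for _ in range(n_errors):
            parent = seqs[rng.integers(n_inputs)]
            pos = int(rng.integers(40))
            alt = rng.choice([b for b in "ACGT" if b != parent[pos]])
            rows.append((parent[:pos] + alt + parent[pos + 1 :], int(rng.poisson(20)) + 3))
        df = pd.DataFrame(rows, columns=["sequence", "reads"])
        windows = {"plateau": (0.0, float(n_inputs)), "shoulder_tail": (float(n_inputs), 1e9)}
        return build_profile(df, windows=windows)

    def test_known_substitutions_attributed(self, rng):
        prof = self._profile_with_errors(rng)
        res = attribute_errors(prof)
        assert res.frac_distance1 >= 0.95
        assert res.distance_hist.get(1, 0) >= 100

    def test_no_errors_no_candidates(self, rng):
        pool = build_input_pool(100, {"BC1-BC1": 1.0}, rng)
        df = pd.DataFrame(
            {"sequence": [m.barcode_pair for m in pool], "reads": 100}
        )
        prof = build_profile(
            df, windows={"plateau": (0.0, 100.0), "shoulder_tail": (100.0, 1e9)}
        )
        res = attribute_errors(prof)
        assert res.n_attributed == 0 and res.f_reads == 0.0

    def test_parents_not_mutually_attributable(self, rng):
        """Plateau sequences differ from each other by far more than one
        substitution, so none is explained by a polymerase error."""
        pool = build_input_pool(200, {"BC1-BC1": 0.5, "BC2-BC2": 0.5}, rng)
        seqs = [m.barcode_pair for m in pool]
        for i in range(0, 200, 20):
            others = seqs[:i] + seqs[i + 1 :]
            assert min_hamming_to_set(seqs[i], others) > 1


class TestAnchorErrors:
    def test_clean_pool_unflagged(self, templates, rng):
        pool = build_input_pool(300, {"BC1-BC1": 0.5, "BC2-BC2": 0.5}, rng)
        df = pd.DataFrame({"sequence": [m.barcode_pair for m in pool], "reads": 1})
        assert len(detect_anchor_errors(df, templates)) == 0

    def test_single_anchor_substitution_flagged(self, templates, rng):
        pool = build_input_pool(1, {"BC1-BC1": 1.0}, rng)
        seq = pool[0].barcode_pair
        a, b = templates["BC1-BC1"].dinucleotide_anchors(0)[0]
        swap = {"A": "C", "G": "T", "C": "A", "T": "G"}  # purine <-> pyrimidine
        mutated = seq[:a] + swap[seq[a]] + seq[a + 1 :]
        df = pd.DataFrame({"sequence": [seq, mutated], "reads": [5, 1]})
        flagged = detect_anchor_errors(df, templates)
        assert list(flagged["sequence"]) == [mutated]

    def test_error_frequency_rises_from_plateau_to_tail(
        self, templates, experiment_profile
    ):
        """In the full synthetic run, anchor-violating rows are depleted in
        the plateau and enriched beyond it."""
        prof = experiment_profile
        flagged = detect_anchor_errors(prof, templates)
        n_plateau = prof.window_mask("plateau").sum()
        in_plateau = (flagged["scaled_rank"] <= prof.windows["plateau"][1]).sum()
        frac_plateau = in_plateau / n_plateau
        frac_tail = (len(flagged) - in_plateau) / (len(prof.df) - n_plateau)
        assert frac_tail > 5 * frac_plateau


class TestErrorLoad:
    def test_zero_error_rate(self):
        load = error_load(2900, 0.0, 1.9, 25)
        assert load.z_k == 0.0 and load.f_k == 0.0

    def test_study_scale_fraction(self):
        load = error_load(2900, 0.0011, 1.9, 25)
        assert load.f_k == pytest.approx(25 * 0.0011 / 1.9, rel=1e-12)
        assert load.f_k == pytest.approx(0.0145, abs=5e-4)

    @pytest.mark.parametrize("params", [(2900, 1e-3, 1.9, 25), (500, 5e-4, 1.5, 30)])
    def test_closed_form_equals_explicit_sum(self, params):
        n0, e, c, k = params
        load = error_load(n0, e, c, k)
        explicit = sum(c ** (k - j) * e * n0 * c ** (j - 1) for j in range(1, k + 1))
        assert load.z_k == pytest.approx(explicit, rel=1e-12)
        assert load.z_k / (n0 * c**k) == pytest.approx(load.f_k, rel=1e-12)


class TestEstimateErrorRate:
    def test_study_scale_inversion(self):
        est = estimate_error_rate(0.016, k=25, c=1.9)
        assert est.e == pytest.approx(0.0012, abs=5e-5)

    def test_per_nucleotide_linearisation(self):
        est = estimate_error_rate(0.0008 * 25 / 1.9, k=25, c=1.9)
        assert est.p_nt_linear == pytest.approx(2.0e-5, rel=1e-9)

    def test_zero_fraction(self):
        assert estimate_error_rate(0.0).e == 0.0


class TestSimulateErroneousPcr:
    def test_no_errors_pure_plateau(self, rng):
        prof = simulate_erroneous_pcr(
            0.0, SequencingModel(target_plateau_reads=500 * 2000.0), rng, N0=500
        )
        assert (prof.df["origin"] == "input").all()

    def test_error_read_fraction_matches_model(self):
        """Erroneous reads accumulate to F = k e / c of input reads."""
        p_nt, c, k, n0 = 2.7e-5, 1.9, 25, 2900
        err = tot = 0.0
        for seed in range(3):
            r = np.random.default_rng(900 + seed)
            prof = simulate_erroneous_pcr(
                p_nt, SequencingModel(target_plateau_reads=n0 * 5000.0), r,
                N0=n0, c=c, cycles=k, deterministic_events=False,
            )
            df = prof.df
            err += df.loc[df["origin"] == "error", "reads"].sum()
            tot += df.loc[df["origin"] == "input", "reads"].sum()
        expected = k * molecule_error_rate(p_nt) / c
        assert err / tot == pytest.approx(expected, rel=0.1)

    def test_error_reads_confined_beyond_plateau(self, rng):
        """Error-origin rows sit at high ranks (bootstrap p < 0.01)."""
        prof = simulate_erroneous_pcr(
            2.7e-5, SequencingModel(target_plateau_reads=2900 * 5000.0), rng, N0=2900
        )
        df = prof.df
        pos = prof.scaled_rank[(df["origin"] == "error").to_numpy()]
        res = bootstrap_uniformity(
            PositionSample(pos, (0.0, float(prof.scaled_rank.max())), reps=2000), rng
        )
        assert res.p_value < 0.01
        plateau_err = (
            df.loc[prof.window_mask("plateau"), "origin"] == "error"
        ).mean()
        assert plateau_err < 0.05


class TestStochasticWithErrors:
    def test_no_errors_reduces_to_stochastic_sampling(self, rng):
        prof = simulate_stochastic_with_errors(
            0.0, SequencingModel(target_plateau_reads=500 * 2000.0), rng,
            N0=500, cycles=12,
        )
        assert (prof.df["origin"] == "input").all()

    def test_profile_has_plateau_shoulder_and_tail(self, experiment_profile):
        """The combined model reproduces the three-regime rank profile:
        a flat plateau, then a shoulder, then a long low-count tail."""
        df = experiment_profile.df
        reads = df["reads"].to_numpy(dtype=float)
        n_in = (df["origin"] == "input").sum()
        plateau = reads[: int(0.8 * n_in)]
        assert plateau.std() / plateau.mean() < 0.5
        assert len(df) > 5 * n_in  # long tail of error rows
        assert np.median(reads[n_in * 3 :]) <= 3

    def test_resampling_preserves_error_fraction(self, rng, experiment_profile):
        """F is invariant under lambda = 0.1 Poisson thinning."""
        raw = attribute_errors(experiment_profile, min_reads=1)
        thinned = poisson_resample(experiment_profile, 0.1, rng)
        res = attribute_errors(thinned, min_reads=1)
        assert res.f_reads == pytest.approx(raw.f_reads, rel=0.15)


class TestSequencingErrorArguments:
    def test_triple_error_probabilities(self):
        assert repeated_sequencing_error_prob(30, 3, 40) == pytest.approx(4e-8)
        per_plateau = repeated_sequencing_error_prob(30, 3, 40) * 1e4
        assert per_plateau == pytest.approx(4e-4)

    def test_min_reads_threshold_rejects_sequencing_errors(
        self, tmp_path, templates, rng
    ):
        """Pipeline on reads with Q30-scale sequencing errors but no
        polymerase errors: no row at three or more reads is flagged."""
        from pcrdistort.preprocess import process_fastq
        from pcrdistort.templates import emit_read_pairs

        pool = build_input_pool(500, {"BC1-BC1": 1.0}, rng)
        rows = pd.DataFrame(
            {
                "sequence": [m.barcode_pair for m in pool],
                "tag": [m.tag for m in pool],
                "read_count": 8,
            }
        )
        t = templates["BC1-BC1"]
        emit_read_pairs(
            rows, t, tmp_path / "r1.fq", tmp_path / "r2.fq", rng, seq_error_rate=1e-3
        )
        table, _ = process_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq", t)
        prof = build_profile(
            table, windows={"plateau": (0.0, 500.0), "shoulder_tail": (500.0, 1e9)}
        )
        res = attribute_errors(prof, min_reads=3)
        assert res.n_attributed == 0
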