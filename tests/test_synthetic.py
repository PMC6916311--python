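"""Ground-truth generators: determinism, analytic expectations, round trips."""

import numpy as np
import pytest

from biasmeta.data_model import (
    BiasDistribution,
    ValidationError,
    read_elicitations,
    read_trials,
    write_elicitations,
    write_trials,
)
from biasmeta.elicitation import process_elicitations
from biasmeta.synthetic import (
    DEFAULT_DOMAIN_PARAMS,
    default_bias_table,
    simulate_elicitations,
    simulate_meta_analysis,
    simulate_meta_epi,
    simulate_opinion_means,
)


class TestMetaAnalysisGenerator:
    def test_same_seed_gives_identical_datasets(self):
        r1, t1 = simulate_meta_analysis(n_trials=8, seed=5)
        r2, t2 = simulate_meta_analysis(n_trials=8, seed=5)
        assert r1 == r2 and t1.biases == t2.biases

    def test_noise_free_limit_recovers_d(self):
        records, truth = simulate_meta_analysis(
            n_trials=6,
            d=-0.4,
            tau=0.0,
            profiles=["LLL"] * 6,
            arm_size_range=(500_000, 500_000),
            seed=1,
        )
        for r in records:
            log_or = np.log(r.events_trt / (r.n_trt - r.events_trt)) - np.log(
                r.events_ctrl / (r.n_ctrl - r.events_ctrl)
            )
            assert log_or == pytest.approx(-0.4, abs=0.05)

    def test_mean_log_or_matches_analytic_expectation(self):
        # law of large numbers over many trials: E[log OR] = d + mean bias
        table = default_bias_table()
        records, truth = simulate_meta_analysis(
            n_trials=10_000,
            d=-0.3,
            tau=0.1,
            profiles=["XLL"] * 10_000,
            arm_size_range=(2000, 2000),
            seed=9,
        )
        log_ors = np.array(
            [
                np.log((r.events_trt + 0.5) / (r.n_trt - r.events_trt + 0.5))
                - np.log((r.events_ctrl + 0.5) / (r.n_ctrl - r.events_ctrl + 0.5))
                for r in records
            ]
        )
        expected = -0.3 + table["XLL"].mean
        mc_sd = log_ors.std() / np.sqrt(len(log_ors))
        assert abs(log_ors.mean() - expected) < 3 * mc_sd + 0.01

    def test_round_trip_through_readers(self, tmp_path):
        records, _ = simulate_meta_analysis(n_trials=8, seed=5)
        p = tmp_path / "trials.csv"
        write_trials(records, p)
        assert read_trials(p) == records

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValidationError):
            simulate_meta_analysis(ctrl_rate_range=(0.0, 0.4))
        with pytest.raises(ValidationError):
            simulate_meta_analysis(n_trials=1)


class TestMetaEpiGenerator:
    def test_every_meta_has_reference_and_flagged_trials(self):
        records, _ = simulate_meta_epi(10, 6, seed=3)
        by_meta = {}
        for r in records:
            by_meta.setdefault(r.meta_id, []).append(r.profile.is_all_low)
        for flags in by_meta.values():
            assert any(flags) and not all(flags)

    def test_zero_variances_give_shared_domain_bias(self):
        params = {d: (b, 0.0, 0.0) for d, (b, _, _) in DEFAULT_DOMAIN_PARAMS.items()}
        records, truth = simulate_meta_epi(5, 6, domain_params=params, seed=4)
        for tid, key in truth.profiles.items():
            expected = sum(
                params[d][0] for d, c in zip(DEFAULT_DOMAIN_PARAMS, key) if c == "X"
            )
            assert truth.biases[tid] == pytest.approx(expected, abs=1e-12)

    def test_flagged_contrast_matches_analytic_expectation(self):
        # across many meta-analyses the mean generated bias per flagged
        # domain approaches b0 (law of large numbers on the truth record)
        records, truth = simulate_meta_epi(1000, 4, seed=6, arm_size_range=(50, 60))
        per_flag = {d: [] for d in DEFAULT_DOMAIN_PARAMS}
        single = {"XLL": "seq_gen", "LXL": "alloc_conc", "LLX": "blinding"}
        for tid, key in truth.profiles.items():
            if key in single:
                per_flag[single[key]].append(truth.biases[tid])
        for domain, vals in per_flag.items():
            b0, phi, kappa = DEFAULT_DOMAIN_PARAMS[domain]
            se = np.sqrt(phi**2 + kappa**2) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - b0) < 4 * se

    def test_same_seed_gives_identical_collection(self):
        r1, _ = simulate_meta_epi(4, 5, seed=7)
        r2, _ = simulate_meta_epi(4, 5, seed=7)
        assert r1 == r2


class TestElicitationGenerator:
    def test_no_disagreement_recovers_true_bias_up_to_rounding(self):
        truth = {"t1": -0.17, "t2": -0.05, "t3": -0.30}
        records = simulate_elicitations(
            truth, assessor_shift_sd=0.0, center_noise_sd=0.0, strategy="a", seed=2
        )
        normals = process_elicitations(records)
        for n in normals:
            assert n.mean == pytest.approx(truth[n.trial_id], abs=0.011)

    def test_round_trip_through_reader(self, tmp_path):
        records = simulate_elicitations({"t1": -0.1, "t2": -0.2}, strategy="b", seed=1)
        p = tmp_path / "e.csv"
        write_elicitations(records, p)
        assert read_elicitations(p) == records

    def test_center_at_reference_mean_selects_symmetric_areas(self):
        ref = {"t1": BiasDistribution(-0.15, 0.12)}
        records = simulate_elicitations(
            {"t1": -0.15}, assessor_shift_sd=0.0, center_noise_sd=0.0,
            strategy="c", seed=3, references=ref,
        )
        for r in records:
            assert r.areas in (("B",), ("C",), ("B", "C"))

    def test_assessor_disagreement_drives_icc_down(self):
        # per-trial disagreement between assessors lowers the ICC relative
        # to a panel that agrees, for the same trials
        from biasmeta.consistency import fit_mixed
        import pandas as pd

        def icc_for(noise):
            rng = np.random.default_rng(44)
            truth = {f"t{i}": float(rng.normal(-0.15, 0.08)) for i in range(15)}
            records = simulate_elicitations(
                truth, n_assessors=4, assessor_shift_sd=0.02,
                center_noise_sd=noise, within_sd=0.15, strategy="a", seed=4,
            )
            normals = process_elicitations(records)
            table = pd.DataFrame(
                {
                    "trial_id": [n.trial_id for n in normals],
                    "assessor_id": [n.assessor_id for n in normals],
                    "mean": [n.mean for n in normals],
                }
            )
            fit = fit_mixed(table)
            return fit.sigma2_trial / (fit.sigma2_trial + fit.sigma2_resid)

        assert icc_for(0.3) < 0.5 < icc_for(0.01)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            simulate_elicitations({"t1": 0.0}, within_sd=0.0)
        with pytest.raises(ValidationError):
            simulate_elicitations({"t1": 0.0}, n_assessors=1)

    def test_strategy_defaults_make_plain_scale_widest(self):
        truth = {"t1": -0.2}
        wide = process_elicitations(simulate_elicitations(truth, strategy="a", seed=5))
        narrow = process_elicitations(simulate_elicitations(truth, strategy="b", seed=5))
        assert np.mean([n.sd for n in wide]) > np.mean([n.sd for n in narrow])


def test_opinion_means_generator_shape_and_truth():
    table, truth = simulate_opinion_means(20, 3, 0.5, 0.4, seed=1)
    assert len(table) == 60
    assert truth.sigma2_trial == pytest.approx(0.25)
    assert set(truth.assessor_effects) == set(table["assessor_id"].unique())
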