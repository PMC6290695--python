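"""Campaign generation, execution, collection and analysis products.

Heavy end-to-end campaigns live in the acceptance suite; here the campaign
analysis is exercised on cheap analytic stub models evaluated over real
Saltelli designs, plus micro ISR campaigns for the orchestration contracts.
"""

import hashlib
import json
from dataclasses import replace

import numpy as np
import pytest

from isrsim.campaign import (CampaignIncompleteError, CampaignResult,
                             analyze_outputs, evaluate_design,
                             generate_campaign, load_campaign,
                             presence_probability, run_campaign,
                             spatial_sensitivity_maps)
from isrsim.presets import coarse_demo
from isrsim.saltelli import (ParameterSpace, aleatory_variance, build_design,
                             default_space, first_order_index, total_index)


def micro_config():
    """Tiny, fast ISR configuration for orchestration tests."""
    cfg = coarse_demo()
    return replace(cfg, total_days=2.0,
                   growth=replace(cfg.growth, step=6.0))


def unit_space(n):
    return ParameterSpace(tuple((f"x{i + 1}", 0.0, 1.0) for i in range(n)))


# ---------------------------------------------------------------------------
# Analysis on stub models
# ---------------------------------------------------------------------------

class TestAnalyzeStubModels:
    def test_constant_model_flags_undefined_indices(self):
        design = build_design(default_space(), 16, seed_root=0)
        values = np.full(design.n_runs, 1.0)
        report = analyze_outputs(design, values, K=50, seed=0)
        assert report["variance"]["value"][0] == 0.0
        assert report["aleatory_variance"]["value"][0] == 0.0
        for i in range(3):
            assert np.isnan(report[f"S_{i}"]["value"][0])
            assert np.isnan(report[f"ST_{i}"]["value"][0])

    def test_single_input_deterministic_model(self):
        """f = deployment depth: S_depth ~ 100%, others ~ 0, no aleatory."""
        design = build_design(default_space(), 2000, seed_root=3)
        values = evaluate_design(design, lambda x, seed: x[1])
        report = analyze_outputs(design, values, K=30, seed=0)
        assert abs(report["S_1"]["value"][0] - 100.0) < 3.0
        assert abs(report["S_0"]["value"][0]) < 3.0
        assert abs(report["S_2"]["value"][0]) < 3.0
        assert report["aleatory_variance"]["value"][0] == 0.0

    def test_additive_noise_share(self):
        """f = x1 + 2 x2 + xi, xi ~ N(0, 1/12): aleatory = 1/6 of variance."""
        design = build_design(unit_space(2), 10_000, seed_root=1)

        def model(x, seed):
            noise = np.random.default_rng(seed).normal(0, np.sqrt(1 / 12))
            return x[0] + 2 * x[1] + noise

        values = evaluate_design(design, model)
        report = analyze_outputs(design, values, K=30, seed=0)
        share = (report["aleatory_variance"]["value"][0]
                 / report["variance"]["value"][0])
        assert abs(share - 1 / 6) < 0.03
        # and the epistemic shares still resolve on top of the noise
        assert abs(report["S_0"]["value"][0] - 100 / 6) < 5.0
        assert abs(report["S_1"]["value"][0] - 400 / 6) < 5.0

    def test_bootstrap_errors_reported_for_every_statistic(self):
        design = build_design(unit_space(2), 200, seed_root=2)
        values = evaluate_design(design, lambda x, seed: x[0])
        report = analyze_outputs(design, values, K=100, seed=0)
        for stats in report.values():
            assert np.all(np.isfinite(stats["bootstrap_sd"])
                          | np.isnan(stats["value"]))


# ---------------------------------------------------------------------------
# Generation and execution
# ---------------------------------------------------------------------------

class TestGenerateCampaign:
    def test_file_count_and_idempotence(self, tmp_path):
        cfg = micro_config()
        d1 = tmp_path / "c1"
        d2 = tmp_path / "c2"
        generate_campaign(cfg, default_space(), 2, 7, d1)
        generate_campaign(cfg, default_space(), 2, 7, d2)
        configs = sorted((d1 / "runs").glob("*/config.toml"))
        assert len(configs) == 16  # M (2n + 2) with M=2, n=3
        h1 = hashlib.sha256((d1 / "design.csv").read_bytes()).hexdigest()
        h2 = hashlib.sha256((d2 / "design.csv").read_bytes()).hexdigest()
        assert h1 == h2
        c1 = (d1 / "runs" / configs[0].parent.name / "config.toml").read_bytes()
        c2 = (d2 / "runs" / configs[0].parent.name / "config.toml").read_bytes()
        assert c1 == c2

    def test_refuses_to_clobber(self, tmp_path):
        cfg = micro_config()
        out = tmp_path / "c"
        generate_campaign(cfg, default_space(), 1, 0, out)
        with pytest.raises(FileExistsError):
            generate_campaign(cfg, default_space(), 1, 0, out)
        generate_campaign(cfg, default_space(), 1, 0, out, overwrite=True)


@pytest.fixture(scope="module")
def executed(tmp_path_factory):
    out = tmp_path_factory.mktemp("campaign")
    generate_campaign(micro_config(), default_space(), 1, 11, out)
    result = run_campaign(out, workers=1)
    return out, result


class TestRunCampaign:
    def test_all_runs_complete(self, executed):
        out, result = executed
        assert result.area.shape[0] == 8
        for rid in result.design.runs["run_id"]:
            status = json.loads((out / "runs" / rid / "status.json").read_text())
            assert status["state"] == "done"

    def test_resumable_skips_done_runs(self, executed):
        out, result = executed
        # mark one run as pending again; rerun touches only that one
        rid = result.design.runs["run_id"].iloc[0]
        mtimes = {r: (out / "runs" / r / "trajectory.csv").stat().st_mtime_ns
                  for r in result.design.runs["run_id"]}
        (out / "runs" / rid / "status.json").unlink()
        result2 = run_campaign(out, workers=1)
        for r in result.design.runs["run_id"]:
            mt = (out / "runs" / r / "trajectory.csv").stat().st_mtime_ns
            assert (mt != mtimes[r]) == (r == rid)
        assert np.array_equal(result.area, result2.area)

    def test_worker_count_invariance(self, executed, tmp_path):
        out, result = executed
        out2 = tmp_path / "c2"
        generate_campaign(micro_config(), default_space(), 1, 11, out2)
        result2 = run_campaign(out2, workers=2)
        assert np.array_equal(result.area, result2.area)
        assert np.array_equal(result.final_snapshots, result2.final_snapshots)

    def test_missing_run_refused_by_loader(self, executed):
        out, result = executed
        rid = result.design.runs["run_id"].iloc[2]
        status = out / "runs" / rid / "status.json"
        saved = status.read_text()
        status.unlink()
        with pytest.raises(CampaignIncompleteError):
            load_campaign(out)
        status.write_text(saved)

    def test_empty_campaign_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            run_campaign(tmp_path / "nothing")


# ---------------------------------------------------------------------------
# Spatial products
# ---------------------------------------------------------------------------

class TestPresenceProbability:
    def test_single_run_binary(self, rng):
        snaps = rng.random((1, 6, 7)) > 0.5
        field = presence_probability(snaps)
        assert set(np.unique(field.data)) <= {0.0, 1.0}

    def test_duplicates_equal_single(self, rng):
        snap = rng.random((1, 6, 7)) > 0.5
        double = np.concatenate([snap, snap])
        assert np.array_equal(presence_probability(double).data,
                              presence_probability(snap).data)

    def test_complementary_masks_give_half(self):
        a = np.zeros((1, 4, 4), bool)
        a[0, ::2, ::2] = True
        b = ~a
        field = presence_probability(np.concatenate([a, b]))
        assert np.all(field.data == 0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            presence_probability(np.zeros((4, 4), bool))


def synthetic_result(rng, M=64, ny=5, nx=6):
    """A CampaignResult whose snapshots come from a known stochastic rule."""
    design = build_design(default_space(), M, seed_root=21)
    snaps = np.zeros((design.n_runs, ny, nx), bool)
    for row in design.runs.itertuples():
        local = np.random.default_rng(row.seed)
        # presence depends on regen_time (column gradient) plus seed noise
        p = (row.regen_time - 15.0) / 8.0
        snaps[row.Index] = local.random((ny, nx)) < p
        snaps[row.Index, :, 0] = True   # always-solid site -> masked
    t = np.array([0.0, 1.0])
    r = design.n_runs
    return CampaignResult(design=design, times=t,
                          area=np.zeros((r, 2)), width=np.zeros((r, 2)),
                          coverage=np.zeros((r, 2)),
                          restenosis=np.zeros(r, bool),
                          final_snapshots=snaps, lattice_spacing=0.02,
                          original_lumen_area=0.38)


class TestSpatialMaps:
    def test_sitewise_matches_scalar_estimators(self, rng, tmp_path):
        result = synthetic_result(rng)
        fields = spatial_sensitivity_maps(result, out_path=tmp_path / "m.h5")
        # independent loop: apply the scalar estimators site by site
        snaps = result.final_snapshots.astype(float)
        r, ny, nx = snaps.shape
        design = result.design
        a_idx = design.block_rows("A").index.to_numpy()
        ar_idx = design.block_rows("A_RESEED").index.to_numpy()
        for y, x in [(1, 2), (3, 4), (0, 0)]:
            site = snaps[:, y, x]
            fa, far = site[a_idx], site[ar_idx]
            if fa.var(ddof=1) == 0:
                assert np.isnan(fields["aleatory_variance"].data[y, x])
                continue
            al, _ = aleatory_variance(fa, far)
            assert fields["aleatory_variance"].data[y, x] == pytest.approx(al)
            for i, name in enumerate(design.names):
                fo = site[design.block_rows("FO", i).index.to_numpy()]
                to = site[design.block_rows("TO", i).index.to_numpy()]
                _, s = first_order_index(fa, fo)
                _, st = total_index(fa, to)
                assert fields[f"FOSI_{name}"].data[y, x] == pytest.approx(s)
                assert fields[f"TSI_{name}"].data[y, x] == pytest.approx(st)

    def test_constant_sites_masked(self, rng):
        result = synthetic_result(rng)
        fields = spatial_sensitivity_maps(result)
        assert np.all(np.isnan(fields["FOSI_regen_time"].data[:, 0]))

    def test_map_dimensions_match_lattice(self, rng, tmp_path):
        result = synthetic_result(rng)
        out = tmp_path / "maps.h5"
        fields = spatial_sensitivity_maps(result, out_path=out)
        import h5py
        with h5py.File(out, "r") as fh:
            for key, field in fields.items():
                assert field.data.shape == result.final_snapshots.shape[1:]
                assert fh[key].shape == field.data.shape

    def test_regen_time_signal_detected(self, rng):
        """The input that drives presence shows the largest mean TSI."""
        result = synthetic_result(rng)
        fields = spatial_sensitivity_maps(result)
        means = {name: np.nanmean(fields[f"TSI_{name}"].data)
                 for name in result.design.names}
        assert means["regen_time"] == max(means.values())
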