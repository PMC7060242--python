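"""Simulator: layout statistics, rendering physics, dose model, experiments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathscore.exceptions import ParameterError
from pathscore.simdata import (DesignItem, DoseModel, SimParams,
                               dose_to_activation, generate_experiment,
                               render_well, sample_layout)

from conftest import SMALL_PARAMS


class TestSampleLayout:
    def test_mean_cell_count_matches_parameters(self):
        params = SimParams(mean_cells=3543, sd_cells=767)
        counts = [sample_layout(params, seed).n_cells for seed in range(40)]
        assert abs(np.mean(counts) - 3543) / 3543 < 0.05

    def test_zero_transfection_rate_gives_no_transfected_cells(self):
        params = SimParams(transfection_rate=0.0, mean_cells=200, sd_cells=10,
                           fov_size=256)
        assert sample_layout(params, 3).n_transfected == 0

    def test_zero_variance_count_is_exact(self):
        params = SimParams(mean_cells=10, sd_cells=0, fov_size=256)
        for seed in range(5):
            assert sample_layout(params, seed).n_cells == 10

    def test_transfected_fraction_near_requested_rate(self):
        truths = [sample_layout(SMALL_PARAMS, s) for s in range(100)]
        frac = sum(t.n_transfected for t in truths) / sum(t.n_cells for t in truths)
        assert abs(frac - 0.12) < 0.015

    def test_nuclei_stay_inside_field(self):
        t = sample_layout(SMALL_PARAMS, 11)
        assert (t.centers - t.radii[:, None] >= 0).all()
        assert (t.centers + t.radii[:, None] <= SMALL_PARAMS.fov_size).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(transfection_rate=1.5)
        with pytest.raises(ParameterError):
            SimParams(mean_cells=-1)
        with pytest.raises(ParameterError):
            SimParams(cytoplasm_radius_factor=0.9)


class TestRenderWell:
    def test_higher_activation_concentrates_reporter_in_nucleus(self):
        truth = sample_layout(SMALL_PARAMS, 5)
        img_lo, t_lo = render_well(truth, 0.0, SMALL_PARAMS, seed=9)
        img_hi, t_hi = render_well(truth, 1.0, SMALL_PARAMS, seed=9)
        # nuclear:cytoplasmic reporter ratio strictly greater at alpha=1
        def ratio(img, t):
            rep = img.channel("reporter")
            nuc_mask = np.zeros(rep.shape, bool)
            for (cy, cx), r in zip(t.centers[t.transfected],
                                   t.radii[t.transfected]):
                yy, xx = np.ogrid[: rep.shape[0], : rep.shape[1]]
                nuc_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            return rep[nuc_mask].sum() / max(rep[~nuc_mask].sum(), 1e-9)

        assert ratio(img_hi, t_hi) > ratio(img_lo, t_lo)

    def test_reporter_total_conserved_across_activation(self):
        # sparse noise-free field: total reporter is independent of alpha
        params = SimParams(fov_size=256, mean_cells=12, sd_cells=0,
                           transfection_rate=1.0,
                           nucleus_radius_range=(4.0, 7.0)).with_noise_off()
        truth = sample_layout(params, 2)
        img0, t0 = render_well(truth, 0.0, params, seed=4)
        img5, t5 = render_well(truth, 0.5, params, seed=4)
        total0 = img0.channel("reporter").astype(np.float64).sum()
        total5 = img5.channel("reporter").astype(np.float64).sum()
        assert total0 == pytest.approx(total5, rel=1e-4)
        np.testing.assert_allclose(t0.reporter_total, t5.reporter_total)

    def test_nuclear_fraction_monotone_in_alpha_on_average(self):
        truth = sample_layout(SMALL_PARAMS, 8)
        fracs = []
        for alpha in (0.0, 0.3, 0.6, 0.9):
            _, t = render_well(truth, alpha, SMALL_PARAMS, seed=1)
            fracs.append(np.nanmean(t.nuclear_fraction))
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_reporter_only_in_transfected_cells(self):
        params = SimParams(fov_size=256, mean_cells=20, sd_cells=0,
                           transfection_rate=0.0).with_noise_off()
        truth = sample_layout(params, 1)
        img, _ = render_well(truth, 0.9, params, seed=1)
        assert img.channel("reporter").max() == 0.0
        assert img.channel("marker").max() == 0.0
        assert img.channel("nuclear").max() > 0.0

    def test_alpha_out_of_range_rejected(self):
        truth = sample_layout(SMALL_PARAMS, 0)
        with pytest.raises(ParameterError):
            render_well(truth, 1.2, SMALL_PARAMS, seed=0)


class TestDoseModel:
    def test_hill_closed_forms(self):
        m = DoseModel(alpha0=0.8, ic50=10.0, hill=1.0, floor=0.0)
        assert dose_to_activation(m, 0.0) == pytest.approx(0.8)
        assert dose_to_activation(m, 10.0) == pytest.approx(0.4)
        assert dose_to_activation(m, 1e9) == pytest.approx(0.0, abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(
        conc=st.lists(st.floats(0, 1e5), min_size=2, max_size=8),
        hill=st.floats(0.5, 3.0),
        ic50=st.floats(0.1, 1e3),
    )
    def test_monotone_decay_without_rebound(self, conc, hill, ic50):
        m = DoseModel(alpha0=0.9, ic50=ic50, hill=hill, floor=0.05)
        c = np.sort(np.asarray(conc))
        a = dose_to_activation(m, c)
        assert (np.diff(a) <= 1e-12).all()
        assert ((a >= 0.05 - 1e-12) & (a <= 0.9 + 1e-12)).all()

    def test_rebound_raises_activation_at_high_dose(self):
        base = DoseModel(alpha0=0.9, ic50=5.0, floor=0.02)
        reb = DoseModel(alpha0=0.9, ic50=5.0, floor=0.02,
                        rebound_amp=0.3, rebound_conc=100.0)
        assert dose_to_activation(reb, 100.0) > dose_to_activation(base, 100.0)
        assert dose_to_activation(reb, 0.0) == pytest.approx(0.9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ParameterError):
            dose_to_activation(DoseModel(), -1.0)


class TestGenerateExperiment:
    def test_counts_plates_and_manifest_shape(self, tmp_path):
        design = [
            DesignItem("KRAS", "WT", "WT", 4, 0.05),
            DesignItem("KRAS", "G12V", "activating", 4, 0.9),
        ]
        man = generate_experiment(design, SMALL_PARAMS, tmp_path, seed=3,
                                  plate_size=4)
        assert len(man) == 8
        assert man["plate_id"].nunique() == 2
        assert (tmp_path / "manifest.csv").exists()
        for p in man["image_path"]:
            assert (tmp_path / p).exists()
        assert set(man.columns) >= {
            "image_path", "plate_id", "well_id", "gene", "variant",
            "annotation_class", "drug", "concentration_nM", "truth_alpha",
        }

    def test_same_seed_is_bit_identical(self, tmp_path):
        design = [DesignItem("KRAS", "WT", "WT", 2, 0.1)]
        a = tmp_path / "a"
        b = tmp_path / "b"
        for d in (a, b):
            generate_experiment(design, SMALL_PARAMS, d, seed=5, plate_size=2)
        for rel in ("images/W0001.tif", "images/W0002.tif"):
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_dose_design_expands_concentration_grid(self, tmp_path):
        dm = DoseModel(alpha0=0.9, ic50=10.0)
        design = [
            DesignItem("cKIT", "D816V", "activating", 2, dm, drug="dasatinib",
                       concentrations=(1.0, 10.0, 100.0)),
        ]
        man = generate_experiment(design, SMALL_PARAMS, tmp_path, seed=1,
                                  plate_size=3)
        assert len(man) == 6
        assert sorted(man["concentration_nM"].unique()) == [1.0, 10.0, 100.0]
        # ground-truth alpha follows the Hill curve
        by_conc = man.groupby("concentration_nM")["truth_alpha"].first()
        assert by_conc.loc[1.0] > by_conc.loc[10.0] > by_conc.loc[100.0]

    def test_empty_design_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            generate_experiment([], SMALL_PARAMS, tmp_path, seed=0)


def test_baseline_oracle_separates_extreme_activations(tmp_path):
    """The non-learned intensity-ratio readout alone fully separates
    wildtype-like from strongly activating wells (AUC 1.0 at n=20/group)."""
    from pathscore.dataio import Dataset
    from pathscore.evaluation import oracle_ratio, pairwise_auc

    design = [
        DesignItem("KRAS", "WT", "WT", 20, 0.05),
        DesignItem("KRAS", "G12V", "activating", 20, 0.9),
    ]
    man = generate_experiment(design, SMALL_PARAMS, tmp_path, seed=21,
                              plate_size=8)
    ds = Dataset(man, tmp_path)
    ratios, labels = [], []
    for i in range(len(ds)):
        res = oracle_ratio(ds.load_image(i))
        assert not res.is_empty
        ratios.append(res.ratio)
        labels.append(int(man.iloc[i]["annotation_class"] != "WT"))
    assert pairwise_auc(ratios, labels) == 1.0
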