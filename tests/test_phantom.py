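"""Phantom generator: dose arithmetic, ground-truth construction, forward models."""

import dataclasses

import numpy as np
import pytest

from dualbolus.aif import evaluate_aif
from dualbolus.dce import T1Map, signal_to_concentration, spgr_signal
from dualbolus.phantom import (
    DEFAULT_CONTRA,
    DEFAULT_DCE_AIF,
    DEFAULT_DCE_PROTOCOL,
    DEFAULT_DSC_AIF,
    DEFAULT_DSC_PROTOCOL,
    DEFAULT_TUMOR,
    AcquisitionProtocol,
    HemodynamicGroundTruth,
    ParameterMaps,
    ROISpec,
    VesselGeometry,
    compute_dose,
    generate_dce_signals,
    generate_dsc_signals,
    make_parameter_maps,
    make_phantom,
    make_study_tables,
)


@pytest.mark.parametrize(
    "stock, dilution, ul_per_g, expected",
    [
        (0.5, 10.0, 3.0, 0.15),   # Magnevist: 10x diluted, 3.0 ul/g
        (1.0, 1.0, 0.0, 0.0),
        (1.0, 4.0, 2.0, 0.5),
    ],
)
def test_dose_arithmetic(stock, dilution, ul_per_g, expected):
    assert compute_dose(stock, dilution, ul_per_g) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [(0.0, 10, 3.0), (0.5, 0.0, 3.0), (0.5, 10, -1.0)])
def test_dose_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        compute_dose(*bad)


class TestParameterMaps:
    def test_zero_heterogeneity_gives_exact_means(self):
        spec = ROISpec(center=(10, 16), radius=6, ktrans_per_min=0.1,
                       ve_frac=0.2, vp_frac=0.02, geometry=None)
        pk = make_parameter_maps(tumor_spec=spec, heterogeneity=0.0, seed=1)
        assert np.all(pk.ktrans_per_min[pk.tumor_mask] == pytest.approx(0.1))
        assert np.all(pk.ve_frac[pk.tumor_mask] == pytest.approx(0.2))

    def test_contralateral_blood_brain_barrier_intact(self):
        """Normal brain keeps a negligible (zero) transfer constant."""
        pk = make_parameter_maps(seed=3)
        assert np.all(pk.ktrans_per_min[pk.contra_mask] == 0.0)
        assert np.all(pk.vp_frac[pk.contra_mask] == DEFAULT_CONTRA.vp_frac)

    def test_seed_determinism(self):
        a = make_parameter_maps(seed=9, heterogeneity=0.3)
        b = make_parameter_maps(seed=9, heterogeneity=0.3)
        assert np.array_equal(a.ktrans_per_min, b.ktrans_per_min)
        assert np.array_equal(a.ve_frac, b.ve_frac)

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_parameter_maps(
                tumor_spec=dataclasses.replace(DEFAULT_TUMOR, center=(16, 16)),
                contra_spec=dataclasses.replace(DEFAULT_CONTRA, center=(18, 16)),
            )

    def test_lognormal_mean_targets_spec_mean(self):
        pk = make_parameter_maps(grid_shape=(64, 64),
                                 tumor_spec=dataclasses.replace(DEFAULT_TUMOR, radius=20, center=(28, 32)),
                                 contra_spec=dataclasses.replace(DEFAULT_CONTRA, center=(56, 56), radius=4),
                                 heterogeneity=0.3, seed=2)
        mean = pk.ktrans_per_min[pk.tumor_mask].mean()
        n = pk.tumor_mask.sum()
        # lognormal(mean 0.1, sigma_log 0.3): SE of the mean ~ 0.1*0.31/sqrt(n)
        assert mean == pytest.approx(DEFAULT_TUMOR.geometry.ktrans_per_min,
                                     abs=4 * 0.1 * 0.31 / np.sqrt(n))

    def test_physical_invariants(self, clean_phantom):
        pk = clean_phantom.truth_pk
        assert np.all(pk.ktrans_per_min >= 0)
        assert np.all(pk.ve_frac + pk.vp_frac <= 1 + 1e-12)
        assert not np.any(pk.tumor_mask & pk.contra_mask)


class TestDCESignals:
    def test_no_agent_no_enhancement(self):
        """ktrans=0, vp=0 voxel stays at baseline for every frame."""
        shape = (16, 16)
        t = np.zeros(shape, bool); t[4, 4] = True
        c = np.zeros(shape, bool); c[10, 10] = True
        pk = ParameterMaps(np.zeros(shape), np.full(shape, 0.2), np.zeros(shape), t, c)
        sig = generate_dce_signals(pk, DEFAULT_DCE_AIF, DEFAULT_DCE_PROTOCOL, 0.0, 0)
        assert np.allclose(sig, sig[..., :1])

    def test_vp_only_voxel_tracks_scaled_aif(self):
        """With ktrans=0, C_t(t) = vp * C_p(t) exactly (recovered by inversion)."""
        shape = (16, 16)
        t = np.zeros(shape, bool); t[4, 4] = True
        c = np.zeros(shape, bool); c[10, 10] = True
        proto = DEFAULT_DCE_PROTOCOL
        pk = ParameterMaps(np.zeros(shape), np.full(shape, 0.2),
                           np.full(shape, 0.05), t, c)
        sig = generate_dce_signals(pk, DEFAULT_DCE_AIF, proto, 0.0, 0)
        t1map = T1Map(np.full(shape, proto.t10_s), np.full(shape, 1000.0))
        conc, valid = signal_to_concentration(sig, t1map, proto, 5)
        cp = evaluate_aif(clean := dataclasses.replace(
            DEFAULT_DCE_AIF, t0_s=proto.inject_time_s), proto.t_s)
        assert valid.all()
        assert np.allclose(conc[4, 4], 0.05 * cp, atol=1e-8)

    def test_baseline_conservation(self, clean_phantom):
        """Noise-free frames at/before injection equal the precontrast SPGR
        baseline computed from (M0, T10, protocol)."""
        proto = clean_phantom.protocol_dce
        expected = spgr_signal(clean_phantom.m0, proto.t10_s, proto)
        pre = clean_phantom.dce_signal[..., : proto.inject_frame]
        assert np.allclose(pre, expected, rtol=1e-10)

    def test_dataset_seed_determinism(self):
        a = make_phantom(snr=30.0, seed=5)
        b = make_phantom(snr=30.0, seed=5)
        assert np.array_equal(a.dce_signal, b.dce_signal)
        assert np.array_equal(a.dsc_signal, b.dsc_signal)
        assert np.array_equal(a.truth_pk.ktrans_per_min, b.truth_pk.ktrans_per_min)


class TestDSCSignals:
    def test_cbf_zero_flat_baseline(self):
        shape = (16, 16)
        hemo = HemodynamicGroundTruth(
            cbf=np.zeros(shape), cbv=np.zeros(shape), mtt_s=np.ones(shape))
        sig = generate_dsc_signals(hemo, DEFAULT_DSC_AIF, DEFAULT_DSC_PROTOCOL, 0.0, 0)
        assert np.allclose(sig, sig[..., :1])

    def test_boxcar_residue_impulse_aif(self):
        """With a near-impulse AIF, a boxcar residue gives a scaled boxcar
        tissue curve of width MTT."""
        from dualbolus.phantom import _tissue_curve_dsc

        dt = 0.5
        t = np.arange(120) * dt
        cp = np.zeros_like(t)
        cp[20] = 1.0  # unit-sample impulse at 10 s
        mtt = 4.0
        curve = _tissue_curve_dsc(2.0, mtt, cp, t, "boxcar")
        # plateau: cbf * (impulse area = dt * 1 via trapezoid) inside the box
        inside = curve[23:27]
        outside = np.concatenate([curve[:19], curve[31:]])
        assert np.allclose(inside, 2.0 * dt * 1.0, rtol=1e-6)
        assert np.allclose(outside, 0.0, atol=1e-12)

    def test_central_volume_theorem(self, clean_phantom):
        """Integral ratio of tissue to AIF concentration equals CBV (<2%)."""
        ds = clean_phantom
        proto = ds.protocol_dsc
        cp = evaluate_aif(ds.aif_dsc, proto.t_s)
        dr2s = -np.log(ds.dsc_signal / ds.dsc_signal[..., :1]) / proto.te_s
        conc = dr2s / proto.r2s_per_mM_s
        tm = ds.truth_pk.tumor_mask
        ratio = np.trapezoid(conc[tm], proto.t_s, axis=-1) / np.trapezoid(cp, proto.t_s)
        rel = np.abs(ratio - ds.truth_hemo.cbv[tm]) / ds.truth_hemo.cbv[tm]
        assert np.median(rel) < 0.02

    def test_truth_satisfies_central_volume_identity(self, clean_phantom):
        th = clean_phantom.truth_hemo
        pos = th.cbf > 0
        assert np.allclose(th.mtt_s[pos], th.cbv[pos] / th.cbf[pos])

    def test_unsupported_residue_shape(self):
        with pytest.raises(ValueError, match="residue_shape"):
            HemodynamicGroundTruth(cbf=np.ones((4, 4)), cbv=np.ones((4, 4)),
                                   mtt_s=np.ones((4, 4)), residue_shape="triangle")


def test_vessel_geometry_scaling_law():
    """Scaling the vessel surface area S scales K^trans and CBV together,
    leaving K^trans/CBV = 4 P_CA/d untouched."""
    g = VesselGeometry(p_ca=0.002, d=0.004, s_per_vol=50.0)
    for c in (0.5, 2.0, 3.7):
        gc = VesselGeometry(p_ca=g.p_ca, d=g.d, s_per_vol=g.s_per_vol * c)
        assert gc.ktrans_per_min == pytest.approx(c * g.ktrans_per_min)
        assert gc.cbv == pytest.approx(c * g.cbv)
        assert gc.ktrans_per_min / gc.cbv == pytest.approx(g.ktrans_per_min / g.cbv)


def test_protocol_validation():
    with pytest.raises(ValueError):
        AcquisitionProtocol(tr_s=0.02, flip_deg=95.0, te_s=0.003, dt_s=3.0,
                            n_frames=80, inject_frame=10)
    with pytest.raises(ValueError):
        AcquisitionProtocol(tr_s=0.02, flip_deg=20.0, te_s=0.003, dt_s=3.0,
                            n_frames=80, inject_frame=80)


def test_study_tables_structure_and_determinism():
    roi_a, growth_a, surv_a = make_study_tables(seed=4)
    roi_b, growth_b, surv_b = make_study_tables(seed=4)
    assert roi_a.equals(roi_b) and growth_a.equals(growth_b) and surv_a.equals(surv_b)
    assert set(surv_a["group"]) == {"untreated", "cediranib", "SC68896", "combo"}
    assert (surv_a["time_days"] > 0).all()
    assert (roi_a["rcbv"] > 0).all()
    # every surviving animal measured at day 0
    assert (roi_a["day"] == 0).sum() == len(surv_a)
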