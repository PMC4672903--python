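"""Synthetic dual-bolus DCE/DSC phantom with known ground truth.

Emulates a single-slice dual-injection perfusion study of an intracranial
mouse glioma: a T1-weighted SPGR series driven by a gadolinium bolus through
the Extended Tofts-Kety model, followed by a T2*-weighted series driven by an
iron-oxide bolus through indicator-dilution theory, over a 2D brain slab
containing a heterogeneous tumor ROI and a normal contralateral ROI, with
Rician magnitude noise.

Ground truth is built from an explicit capillary geometry: under the
cylindrical-vessel approximation the transfer constant is the
permeability-surface product, K^trans = P_CA * S, while the blood volume is
CBV = S * d / 4 (S the total vessel surface area per unit tissue volume, d
the average capillary diameter).  Hence K^trans / CBV = 4 * P_CA / d: the
ratio responds to wall permeability and vessel caliber but not to how much
vasculature there is.  Scaling S scales both K^trans and CBV and leaves the
ratio fixed — the decoupling property the downstream analysis quantifies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aif import AIFParams, evaluate_aif
from .dce import ToftsParams, extended_tofts_forward, spgr_signal, exp_convolve

__all__ = [
    "AcquisitionProtocol",
    "ParameterMaps",
    "HemodynamicGroundTruth",
    "VesselGeometry",
    "PhantomDataset",
    "ROISpec",
    "GroupSpec",
    "compute_dose",
    "make_parameter_maps",
    "generate_dce_signals",
    "generate_dsc_signals",
    "make_phantom",
    "make_study_tables",
    "add_rician_noise",
    "DEFAULT_DCE_PROTOCOL",
    "DEFAULT_DSC_PROTOCOL",
    "DEFAULT_DCE_AIF",
    "DEFAULT_DSC_AIF",
    "DEFAULT_GROUPS",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scanner and injection constants shared by forward and inverse models.

    tr_s : repetition time (s).
    flip_deg : excitation flip angle (degrees), in (0, 90].
    te_s : echo time (s) — used by the T2* conversion only.
    dt_s : dynamic frame interval (s).
    n_frames : number of dynamic frames.
    inject_frame : frame index of bolus arrival.
    r1_per_mM_s : longitudinal relaxivity of the T1 agent (mM^-1 s^-1).
    r2s_per_mM_s : effective transverse relaxivity of the susceptibility
        agent (mM^-1 s^-1).
    t10_s : default precontrast tissue T1 (s).
    """

    tr_s: float
    flip_deg: float
    te_s: float
    dt_s: float
    n_frames: int
    inject_frame: int
    r1_per_mM_s: float = 3.2
    r2s_per_mM_s: float = 100.0
    t10_s: float = 1.8

    def __post_init__(self) -> None:
        for name in ("tr_s", "te_s", "dt_s", "r1_per_mM_s", "r2s_per_mM_s", "t10_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.flip_deg <= 90:
            raise ValueError("flip_deg must be in (0, 90]")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not 0 <= self.inject_frame < self.n_frames:
            raise ValueError("inject_frame must satisfy 0 <= inject_frame < n_frames")

    @property
    def t_s(self) -> np.ndarray:
        """Frame-time vector in seconds."""
        return np.arange(self.n_frames) * self.dt_s

    @property
    def inject_time_s(self) -> float:
        return self.inject_frame * self.dt_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)


# Defaults modeled on a single-slice small-animal dual-bolus session at high
# field: a FLASH DCE series (TR 20 ms, flip 20 deg, one frame every 3 s, 4 min)
# and a faster T2*-weighted DSC series (one frame every 0.5 s, 1 min).
DEFAULT_DCE_PROTOCOL = AcquisitionProtocol(
    tr_s=0.02, flip_deg=20.0, te_s=0.003, dt_s=3.0, n_frames=80, inject_frame=10,
)
DEFAULT_DSC_PROTOCOL = AcquisitionProtocol(
    tr_s=0.01, flip_deg=15.0, te_s=0.012, dt_s=0.5, n_frames=120, inject_frame=20,
)
DEFAULT_DCE_AIF = AIFParams(
    amp_mM=5.0, t0_s=DEFAULT_DCE_PROTOCOL.inject_time_s,
    alpha=2.0, beta=3.5, washout_frac=0.12, washout_rate_per_s=0.008,
)
DEFAULT_DSC_AIF = AIFParams(
    amp_mM=8.0, t0_s=DEFAULT_DSC_PROTOCOL.inject_time_s,
    alpha=2.5, beta=1.5, washout_frac=0.05, washout_rate_per_s=0.02,
)


@dataclass
class ParameterMaps:
    """Voxelwise Extended Tofts-Kety maps with tumor/contralateral masks."""

    ktrans_per_min: np.ndarray
    ve_frac: np.ndarray
    vp_frac: np.ndarray
    tumor_mask: np.ndarray
    contra_mask: np.ndarray

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.contra_mask = np.asarray(self.contra_mask, dtype=bool)
        if np.any(self.ktrans_per_min < 0):
            raise ValueError("ktrans must be nonnegative")
        if np.any(self.ve_frac < 0) or np.any(self.vp_frac < 0):
            raise ValueError("ve and vp must be nonnegative")
        if np.any(self.ve_frac + self.vp_frac > 1.0 + 1e-12):
            raise ValueError("ve + vp must not exceed 1")
        if np.any(self.tumor_mask & self.contra_mask):
            raise ValueError("tumor and contralateral masks overlap")
        if not self.tumor_mask.any() or not self.contra_mask.any():
            raise ValueError("masks must be nonempty")


@dataclass
class HemodynamicGroundTruth:
    """True CBF/CBV/MTT maps; MTT = CBV/CBF holds exactly by construction."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt_s: np.ndarray
    residue_shape: str = "exponential"

    def __post_init__(self) -> None:
        if self.residue_shape not in ("exponential", "boxcar"):
            raise ValueError(f"unsupported residue_shape {self.residue_shape!r}")
        for name in ("cbf", "cbv", "mtt_s"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        pos = self.cbf > 0
        if not np.allclose(self.mtt_s[pos], self.cbv[pos] / self.cbf[pos]):
            raise ValueError("mtt must equal cbv/cbf where cbf > 0")


@dataclass(frozen=True)
class VesselGeometry:
    """Capillary-bed description in arbitrary consistent units.

    p_ca : wall permeability coefficient of the contrast agent (length/time).
    d : average capillary diameter (length).
    s_per_vol : total vessel surface area per unit tissue volume (1/length).

    Under the cylindrical-vessel assumption CBV = s_per_vol * d / 4 and
    K^trans = p_ca * s_per_vol, so K^trans/CBV = 4 p_ca / d.
    """

    p_ca: float
    d: float
    s_per_vol: float

    def __post_init__(self) -> None:
        if min(self.p_ca, self.d, self.s_per_vol) <= 0:
            raise ValueError("all vessel-geometry fields must be positive")

    @property
    def ktrans_per_min(self) -> float:
        return self.p_ca * self.s_per_vol

    @property
    def cbv(self) -> float:
        return self.s_per_vol * self.d / 4.0


@dataclass
class PhantomDataset:
    """One synthetic animal: paired DCE+DSC series with full ground truth."""

    protocol_dce: AcquisitionProtocol
    protocol_dsc: AcquisitionProtocol
    dce_signal: np.ndarray
    dsc_signal: np.ndarray
    truth_pk: ParameterMaps
    truth_hemo: HemodynamicGroundTruth
    aif_dce: AIFParams
    aif_dsc: AIFParams
    m0: float
    seed: int


# ---------------------------------------------------------------------------
# Dose bookkeeping
# ---------------------------------------------------------------------------


def compute_dose(stock_mmol_per_ml: float, dilution_factor: float, ul_per_g: float) -> float:
    """Injected dose in mmol/kg.

    ``(stock / dilution) [mmol/ml] * volume-per-mass [ul/g == ml/kg]``; the
    microliter-per-gram to milliliter-per-kilogram conversion is exactly 1.
    """
    if stock_mmol_per_ml <= 0 or dilution_factor <= 0:
        raise ValueError("stock concentration and dilution factor must be positive")
    if ul_per_g < 0:
        raise ValueError("injection volume must be nonnegative")
    return (stock_mmol_per_ml / dilution_factor) * ul_per_g


# ---------------------------------------------------------------------------
# Parameter-map generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI with mean kinetic/hemodynamic parameters.

    Means are the centers of the voxelwise log-normal draws; ``mtt_s`` and
    ``geometry`` feed the hemodynamic truth.
    """

    center: tuple[int, int]
    radius: int
    ktrans_per_min: float = 0.1
    ve_frac: float = 0.2
    vp_frac: float = 0.02
    mtt_s: float = 3.0
    geometry: VesselGeometry | None = None


# Tumor truth centered on the early-stage glioma operating point
# (K^trans ~ 0.1 min^-1); contralateral normal brain has an intact
# blood-brain barrier (K^trans = 0) and a small fixed plasma fraction.
DEFAULT_TUMOR = ROISpec(
    center=(10, 16), radius=6,
    geometry=VesselGeometry(p_ca=0.002, d=0.004, s_per_vol=50.0),
    mtt_s=3.0,
)
DEFAULT_CONTRA = ROISpec(
    center=(23, 16), radius=5,
    ktrans_per_min=0.0, ve_frac=0.2, vp_frac=0.01,
    geometry=VesselGeometry(p_ca=1e-9, d=0.004, s_per_vol=20.0),
    mtt_s=1.5,
)


def _disk(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_parameter_maps(
    grid_shape: tuple[int, int] = (32, 32),
    tumor_spec: ROISpec = DEFAULT_TUMOR,
    contra_spec: ROISpec = DEFAULT_CONTRA,
    heterogeneity: float = 0.3,
    seed: int = 0,
) -> ParameterMaps:
    """Draw voxelwise Tofts maps on a 2D grid.

    Tumor voxels draw K^trans, v_e, v_p from log-normal distributions whose
    *mean* equals the spec value and whose log-SD is ``heterogeneity``
    (0 gives exactly the mean in every voxel).  Contralateral voxels get the
    spec values verbatim: K^trans = 0 with a small fixed v_p, mimicking
    intact blood-brain barrier.  Deterministic under ``seed``.
    """
    if min(grid_shape) < 16:
        raise ValueError("grid must be at least 16x16")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    tumor_ktrans = (
        tumor_spec.geometry.ktrans_per_min if tumor_spec.geometry else tumor_spec.ktrans_per_min
    )
    if tumor_ktrans <= 0 or tumor_spec.ve_frac <= 0 or tumor_spec.vp_frac <= 0:
        raise ValueError("tumor spec means must be positive")
    tumor = _disk(grid_shape, tumor_spec.center, tumor_spec.radius)
    contra = _disk(grid_shape, contra_spec.center, contra_spec.radius)
    if np.any(tumor & contra):
        raise ValueError("tumor and contralateral ROIs overlap")
    if not tumor.any() or not contra.any():
        raise ValueError("ROIs fall outside the grid")

    rng = np.random.default_rng(seed)
    ktrans = np.zeros(grid_shape)
    ve = np.full(grid_shape, 0.2)
    vp = np.full(grid_shape, 0.01)

    n = int(tumor.sum())

    def lognormal_mean(mean, sigma, size):
        if sigma == 0:
            return np.full(size, mean)
        # mu chosen so the distribution mean (not median) equals `mean`
        mu = np.log(mean) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, size)

    ktrans[tumor] = lognormal_mean(tumor_ktrans, heterogeneity, n)
    ve[tumor] = np.clip(lognormal_mean(tumor_spec.ve_frac, heterogeneity, n), 1e-3, 0.8)
    vp_geom = (
        tumor_spec.geometry.cbv if tumor_spec.geometry else tumor_spec.vp_frac
    )
    vp[tumor] = np.clip(lognormal_mean(vp_geom, heterogeneity, n), 1e-4, 0.2)
    # keep ve + vp physical
    over = ve + vp > 1.0
    ve[over] = 1.0 - vp[over]

    ktrans[contra] = contra_spec.ktrans_per_min
    ve[contra] = contra_spec.ve_frac
    vp[contra] = contra_spec.vp_frac

    return ParameterMaps(ktrans, ve, vp, tumor, contra)


def make_hemodynamic_truth(
    pk: ParameterMaps,
    tumor_spec: ROISpec = DEFAULT_TUMOR,
    contra_spec: ROISpec = DEFAULT_CONTRA,
    residue_shape: str = "exponential",
) -> HemodynamicGroundTruth:
    """Hemodynamic truth tied to the same vessel geometry as the PK maps.

    Tumor CBV is made proportional to the voxelwise K^trans draw (both scale
    with local vessel surface area S), anchored so the tumor-mean CBV equals
    the geometry value S*d/4; MTT is uniform per region and CBF = CBV/MTT.
    """
    shape = pk.ktrans_per_min.shape
    cbv = np.zeros(shape)
    mtt = np.ones(shape)
    tg = tumor_spec.geometry or VesselGeometry(0.002, 0.004, 50.0)
    cg = contra_spec.geometry or VesselGeometry(1e-9, 0.004, 20.0)
    tumor, contra = pk.tumor_mask, pk.contra_mask
    kt = pk.ktrans_per_min[tumor]
    mean_kt = kt.mean() if kt.mean() > 0 else 1.0
    cbv[tumor] = tg.cbv * kt / mean_kt  # local S variation drives both
    cbv[contra] = cg.cbv
    mtt[tumor] = tumor_spec.mtt_s
    mtt[contra] = contra_spec.mtt_s
    background = ~(tumor | contra)
    cbv[background] = cg.cbv
    mtt[background] = contra_spec.mtt_s
    cbf = np.where(mtt > 0, cbv / mtt, 0.0)
    return HemodynamicGroundTruth(cbf=cbf, cbv=cbv, mtt_s=mtt, residue_shape=residue_shape)


# ---------------------------------------------------------------------------
# Forward signal generation
# ---------------------------------------------------------------------------


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    """Magnitude-MRI (Rician) noise: |signal + n1 + i*n2| with n ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re**2 + im**2)


def generate_dce_signals(
    truth_pk: ParameterMaps,
    aif_truth: AIFParams,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
    m0: float = 1000.0,
) -> np.ndarray:
    """Forward-simulate the T1-weighted SPGR series, time on the last axis.

    Per voxel: C_t(t) from the Extended Tofts-Kety model, R1(t) = 1/T10 +
    r1*C_t, SPGR signal, then Rician noise.  Frames before ``inject_frame``
    carry baseline signal only (the AIF arrival time is pinned to the
    injection frame).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    t_s = protocol.t_s
    t_min = t_s / 60.0
    cp = evaluate_aif(dataclasses.replace(aif_truth, t0_s=protocol.inject_time_s), t_s)
    shape = truth_pk.ktrans_per_min.shape
    conc = np.zeros(shape + (protocol.n_frames,))
    for idx in np.ndindex(*shape):
        p = ToftsParams(
            max(float(truth_pk.ktrans_per_min[idx]), 0.0),
            float(truth_pk.ve_frac[idx]) if truth_pk.ktrans_per_min[idx] > 0 else 1.0,
            float(truth_pk.vp_frac[idx]),
        )
        conc[idx] = extended_tofts_forward(p, cp, t_min)
    r1 = 1.0 / protocol.t10_s + protocol.r1_per_mM_s * conc
    signal = spgr_signal(m0, 1.0 / r1, protocol)
    rng = np.random.default_rng(seed)
    return add_rician_noise(signal, noise_sigma, rng)


def _tissue_curve_dsc(cbf, mtt, cp, t_s, residue_shape):
    """CBF * (AIF (*) R)(t) for one voxel (concentration units)."""
    if cbf <= 0:
        return np.zeros_like(t_s)
    if residue_shape == "exponential":
        return cbf * exp_convolve(cp, 1.0 / mtt, t_s)
    if residue_shape == "boxcar":
        # R = 1 on [0, mtt): convolution = integral of cp over [t-mtt, t]
        dt = t_s[1] - t_s[0]
        cum = np.concatenate([[0.0], np.cumsum(0.5 * dt * (cp[:-1] + cp[1:]))])
        shift = mtt / dt
        idx = np.arange(t_s.size) - shift
        lower = np.interp(np.clip(idx, 0, None), np.arange(t_s.size), cum)
        return cbf * (cum - lower)
    raise ValueError(f"unsupported residue_shape {residue_shape!r}")


def generate_dsc_signals(
    truth_hemo: HemodynamicGroundTruth,
    aif_truth: AIFParams,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
    s0: float = 1000.0,
) -> np.ndarray:
    """Forward-simulate the T2*-weighted bolus-tracking series.

    Tissue concentration C(t) = CBF * (AIF (*) R)(t) with R exponential or
    boxcar of width MTT; signal S = S0 * exp(-TE * r2s * C); Rician noise.
    CBV = CBF * MTT holds by construction of the truth maps.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    t_s = protocol.t_s
    cp = evaluate_aif(dataclasses.replace(aif_truth, t0_s=protocol.inject_time_s), t_s)
    shape = truth_hemo.cbf.shape
    signal = np.empty(shape + (protocol.n_frames,))
    for idx in np.ndindex(*shape):
        c = _tissue_curve_dsc(
            float(truth_hemo.cbf[idx]), float(truth_hemo.mtt_s[idx]),
            cp, t_s, truth_hemo.residue_shape,
        )
        signal[idx] = s0 * np.exp(-protocol.te_s * protocol.r2s_per_mM_s * c)
    rng = np.random.default_rng(seed)
    return add_rician_noise(signal, noise_sigma, rng)


def make_phantom(
    grid_shape: tuple[int, int] = (32, 32),
    tumor_spec: ROISpec = DEFAULT_TUMOR,
    contra_spec: ROISpec = DEFAULT_CONTRA,
    heterogeneity: float = 0.3,
    snr: float | None = 30.0,
    seed: int = 0,
    protocol_dce: AcquisitionProtocol = DEFAULT_DCE_PROTOCOL,
    protocol_dsc: AcquisitionProtocol = DEFAULT_DSC_PROTOCOL,
    aif_dce: AIFParams = DEFAULT_DCE_AIF,
    aif_dsc: AIFParams = DEFAULT_DSC_AIF,
    residue_shape: str = "exponential",
    m0: float = 1000.0,
) -> PhantomDataset:
    """Generate one complete dual-bolus dataset.

    ``snr`` is the baseline-signal-to-noise ratio (sigma = baseline/snr);
    ``snr=None`` gives noise-free series.  All randomness derives from
    ``seed``; identical seeds reproduce the dataset bit-identically.
    """
    ss = np.random.SeedSequence(seed)
    seed_maps, seed_dce, seed_dsc = [int(s) for s in ss.generate_state(3) >> 1]
    pk = make_parameter_maps(grid_shape, tumor_spec, contra_spec, heterogeneity, seed_maps)
    hemo = make_hemodynamic_truth(pk, tumor_spec, contra_spec, residue_shape)

    base_dce = float(spgr_signal(m0, protocol_dce.t10_s, protocol_dce))
    sigma_dce = 0.0 if snr is None else base_dce / snr
    dce = generate_dce_signals(pk, aif_dce, protocol_dce, sigma_dce, seed_dce, m0)
    sigma_dsc = 0.0 if snr is None else m0 / snr
    dsc = generate_dsc_signals(hemo, aif_dsc, protocol_dsc, sigma_dsc, seed_dsc, m0)

    return PhantomDataset(
        protocol_dce=protocol_dce, protocol_dsc=protocol_dsc,
        dce_signal=dce, dsc_signal=dsc,
        truth_pk=pk, truth_hemo=hemo,
        aif_dce=dataclasses.replace(aif_dce, t0_s=protocol_dce.inject_time_s),
        aif_dsc=dataclasses.replace(aif_dsc, t0_s=protocol_dsc.inject_time_s),
        m0=m0, seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic longitudinal study tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-group study conditions for the synthetic cohort.

    ``k_per_day`` is the exponential tumor-growth rate constant;
    ``median_survival_days`` centers the survival-time draws; ``rcbv_by_day``
    gives the group-level relative-blood-volume trajectory at the imaging
    days, from which K^trans follows via the shared K^trans/rCBV constant
    (vessel-surface-area-driven K^trans variation).
    """

    name: str
    n: int
    k_per_day: float
    median_survival_days: float
    survival_sd_days: float
    rcbv_by_day: dict[int, float]
    rmtt_by_day: dict[int, float]
    ratio_scale: float = 1.0  # group-level P_CA/d multiplier


# Cohort emulating a four-arm preclinical trial: an untreated arm with
# rapidly increasing perfusion, two ineffective monotherapy arms, and a
# combination arm with flat hemodynamics and doubled survival.
DEFAULT_GROUPS = (
    GroupSpec("untreated", 4, 0.21, 13.5, 1.0,
              {0: 2.4, 10: 4.2}, {0: 1.05, 10: 1.5}),
    GroupSpec("cediranib", 5, 0.19, 13.0, 1.6,
              {0: 2.4, 10: 3.4}, {0: 1.05, 10: 1.4}),
    GroupSpec("SC68896", 4, 0.21, 13.0, 2.8,
              {0: 2.5, 10: 4.6}, {0: 1.05, 10: 2.2}, ratio_scale=1.25),
    GroupSpec("combo", 5, 0.14, 26.0, 2.0,
              {0: 2.4, 10: 2.4, 25: 2.4}, {0: 1.05, 10: 1.1, 25: 1.3}),
)

# shared K^trans/rCBV constant (min^-1 per unit rCBV): 4*P_CA/d in the
# contralateral-normalized convention, anchored so rCBV ~ 2.5 gives
# K^trans ~ 0.1 min^-1 at the pretreatment time point
KTRANS_PER_RCBV = 0.04


def make_study_tables(
    seed: int = 0,
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS,
    v0_mm3: float = 3.0,
    volume_noise: float = 0.10,
    roi_noise: float = 0.10,
    measure_every_days: float = 3.5,
):
    """Synthesize per-animal longitudinal tables for the four-arm study.

    Returns ``(roi_df, growth_df, survival_df)``:

    * ``roi_df`` — one row per animal-day with mean tumor K^trans, rCBF,
      rCBV, rMTT and tumor volume (imaging days 0/10/25, restricted to days
      the animal survives);
    * ``growth_df`` — twice-weekly tumor volumes with ``volume_noise``
      multiplicative log-normal noise around exponential growth;
    * ``survival_df`` — one row per animal with event time in days (all
      events observed: animals are sacrificed at a humane endpoint).
    """
    rng = np.random.default_rng(seed)
    roi_rows, growth_rows, surv_rows = [], [], []
    for g in groups:
        for i in range(g.n):
            animal = f"{g.name}-{i + 1}"
            t_death = max(float(rng.normal(g.median_survival_days, g.survival_sd_days)), 2.0)
            surv_rows.append({"animal_id": animal, "group": g.name,
                              "time_days": round(t_death, 1), "event": 1})
            days = np.arange(0.0, t_death + 1e-9, measure_every_days)
            vols = v0_mm3 * np.exp(g.k_per_day * days) * rng.lognormal(
                0.0, volume_noise, days.size
            )
            for d, v in zip(days, vols):
                growth_rows.append({"animal_id": animal, "group": g.name,
                                    "day": float(d), "volume_mm3": float(v)})
            for day, rcbv_mean in g.rcbv_by_day.items():
                if day > t_death:
                    continue
                rcbv = rcbv_mean * rng.lognormal(0.0, roi_noise)
                rmtt = g.rmtt_by_day[day] * rng.lognormal(0.0, roi_noise)
                rcbf = rcbv / rmtt
                ktrans = KTRANS_PER_RCBV * g.ratio_scale * rcbv * rng.lognormal(0.0, roi_noise / 2)
                vol = v0_mm3 * np.exp(g.k_per_day * day)
                roi_rows.append({
                    "animal_id": animal, "group": g.name, "day": float(day),
                    "mean_ktrans_per_min": float(ktrans), "rcbf": float(rcbf),
                    "rcbv": float(rcbv), "rmtt": float(rmtt),
                    "tumor_volume_mm3": float(vol),
                })
    return (
        pd.DataFrame(roi_rows),
        pd.DataFrame(growth_rows),
        pd.DataFrame(surv_rows),
    )
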