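"""DSC bolus-tracking analysis: ΔR2* conversion, CBV, CBF, MTT, relative maps.

The susceptibility bolus is quantified through the standard chain:

* ΔR2*(t) = -ln(S(t)/S_baseline) / TE, proportional to tissue concentration;
* CBV from the ratio of the tissue to the reference (arterial or
  reference-region) ΔR2* time integrals over the first pass;
* CBF by deconvolution of the tissue curve with the input curve using a
  block-circulant (delay-insensitive) truncated SVD;
* MTT = CBV / CBF (central volume theorem).

Absolute calibration constants (tissue density, hematocrit) are omitted:
all maps are reported relative to the mean over a contralateral normal-brain
ROI, which cancels every proportionality constant and is all the downstream
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HemodynamicMaps",
    "signal_to_dr2star",
    "compute_cbv",
    "deconvolve_cbf",
    "compute_mtt",
    "relative_maps",
    "dsc_analysis",
]

CBF_EPS_FRAC = 1e-6  # cbf > eps gate as a fraction of the map max


@dataclass
class HemodynamicMaps:
    """Absolute and contralateral-relative hemodynamic maps.

    ``cbf``/``cbv`` are in arbitrary consistent units, ``mtt_s`` in seconds;
    ``rcbf``/``rcbv``/``rmtt`` are unitless (contralateral ROI mean == 1).
    ``valid`` flags voxels where the CBF deconvolution and the MTT ratio are
    trustworthy.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt_s: np.ndarray
    rcbf: np.ndarray | None = None
    rcbv: np.ndarray | None = None
    rmtt: np.ndarray | None = None
    valid: np.ndarray | None = None


def signal_to_dr2star(dsc_series: np.ndarray, te_s: float, baseline_frames: int):
    """ΔR2*(t) = -ln(S(t)/mean(S_baseline)) / TE.

    Returns ``(dr2s, valid)``; nonpositive signal samples are flagged and
    clamped (NaN) rather than raising.
    """
    dsc_series = np.asarray(dsc_series, dtype=float)
    if baseline_frames < 1:
        raise ValueError("need at least one baseline frame")
    base = dsc_series[..., :baseline_frames].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline signal must be positive")
    valid = dsc_series > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = np.where(valid, -np.log(np.where(valid, dsc_series, 1.0) / base) / te_s, np.nan)
    return dr2s, valid


def _window_slice(t_s: np.ndarray, window: tuple[float, float] | None):
    if window is None:
        return slice(None)
    lo, hi = window
    idx = np.nonzero((t_s >= lo) & (t_s <= hi))[0]
    if idx.size < 3:
        raise ValueError("integration window covers fewer than 3 frames")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def compute_cbv(
    dr2s_tissue: np.ndarray,
    dr2s_reference: np.ndarray,
    t_s: np.ndarray,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """CBV proportional to the tissue/reference area ratio.

    ``cbv = trapz(tissue) / trapz(reference)`` over the first-pass window
    (seconds); with a reference-region input the proportionality constant is
    exactly the reference CBV and cancels on contralateral normalization.
    """
    t_s = np.asarray(t_s, dtype=float)
    sl = _window_slice(t_s, window)
    ref_area = float(np.trapezoid(np.asarray(dr2s_reference, dtype=float)[sl], t_s[sl]))
    if ref_area == 0:
        raise ValueError("reference curve integrates to zero")
    tis = np.asarray(dr2s_tissue, dtype=float)
    return np.trapezoid(tis[..., sl], t_s[sl], axis=-1) / ref_area


def deconvolve_cbf(
    dr2s_tissue: np.ndarray,
    dr2s_aif: np.ndarray,
    t_s: np.ndarray,
    svd_threshold: float = 0.05,
):
    """CBF by block-circulant truncated-SVD deconvolution.

    Solves ``C_t = dt * (C_a (*) f)`` for the flow-scaled residue
    ``f = CBF * R`` on a zero-padded circulant grid (length 2N), zeroing
    singular values below ``svd_threshold * max``; CBF is the maximum of the
    recovered f, which is delay-insensitive by circularity.

    Returns ``(cbf, residue)`` where ``residue`` has the padded length on
    the last axis.
    """
    if not 0.0 < svd_threshold < 1.0:
        raise ValueError("svd_threshold must be in (0, 1)")
    t_s = np.asarray(t_s, dtype=float)
    dt = np.diff(t_s)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time grid must be uniform")
    dt = float(dt[0])
    ca = np.asarray(dr2s_aif, dtype=float)
    n = ca.size
    if np.linalg.norm(ca) < 1e-12 * max(np.abs(ca).max(initial=0.0), 1.0) or not np.any(ca):
        raise ValueError("degenerate AIF (near-zero norm)")
    m = 2 * n
    ca_pad = np.concatenate([ca, np.zeros(n)])
    # circulant matrix D[i, j] = dt * ca_pad[(i - j) mod m]
    idx = (np.arange(m)[:, None] - np.arange(m)[None, :]) % m
    d_mat = dt * ca_pad[idx]
    u, s, vt = np.linalg.svd(d_mat)
    keep = s > svd_threshold * s[0]
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)

    tis = np.asarray(dr2s_tissue, dtype=float)
    spatial = tis.shape[:-1]
    flat = tis.reshape(-1, tis.shape[-1])
    flat = np.nan_to_num(flat, nan=0.0)
    padded = np.concatenate([flat, np.zeros((flat.shape[0], n))], axis=1)
    # f = V diag(s_inv) U^T c for every voxel at once
    f = (vt.T * s_inv) @ (u.T @ padded.T)
    f = f.T
    cbf = f.max(axis=1)
    return cbf.reshape(spatial), f.reshape(spatial + (m,))


def compute_mtt(cbv: np.ndarray, cbf: np.ndarray):
    """MTT = CBV / CBF (s when CBV and CBF share a time base).

    Voxels with ``cbf <= eps`` (eps = 1e-6 of the map max) are flagged
    invalid and get MTT 0 instead of raising.
    """
    cbv = np.asarray(cbv, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if cbv.shape != cbf.shape:
        raise ValueError("cbv and cbf shapes differ")
    eps = CBF_EPS_FRAC * max(float(np.nanmax(cbf, initial=0.0)), 0.0)
    valid = cbf > eps
    mtt = np.where(valid, cbv / np.where(valid, cbf, 1.0), 0.0)
    return mtt, valid


def relative_maps(
    maps: dict[str, np.ndarray],
    contra_mask: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Normalize each map by its contralateral-ROI mean.

    After normalization the contralateral mean of every returned map is
    exactly 1; global rescaling of an input map leaves its relative map
    unchanged.
    """
    contra_mask = np.asarray(contra_mask, dtype=bool)
    if valid is not None:
        contra_mask = contra_mask & valid
    if not contra_mask.any():
        raise ValueError("contralateral mask empty after flag exclusion")
    out = {}
    for name, m in maps.items():
        m = np.asarray(m, dtype=float)
        ref = float(m[contra_mask].mean())
        if ref <= 0:
            raise ValueError(f"nonpositive contralateral mean for {name}")
        out["r" + name] = m / ref
    return out


def dsc_analysis(
    dsc_series: np.ndarray,
    protocol,
    contra_mask: np.ndarray,
    baseline_frames: int | None = None,
    svd_threshold: float = 0.05,
    reference: str = "contralateral",
    aif_curve: np.ndarray | None = None,
    window_s: float = 60.0,
) -> HemodynamicMaps:
    """Full DSC chain: ΔR2* → CBV, CBF, MTT → contralateral-relative maps.

    ``reference`` selects the deconvolution/normalization input curve:
    ``"contralateral"`` uses the mean ΔR2* over ``contra_mask`` (no artery
    needed in the slice); ``"aif"`` uses ``aif_curve`` (ΔR2* units).  The
    integration window runs from the injection frame to injection +
    ``window_s`` seconds, clipped to the series.
    """
    if baseline_frames is None:
        baseline_frames = max(int(protocol.inject_frame) - 1, 1)
    t_s = protocol.t_s
    dr2s, valid_sig = signal_to_dr2star(dsc_series, protocol.te_s, baseline_frames)
    dr2s = np.nan_to_num(dr2s, nan=0.0)
    if reference == "contralateral":
        ref_curve = dr2s[contra_mask].mean(axis=0)
    elif reference == "aif":
        if aif_curve is None:
            raise ValueError("reference='aif' requires aif_curve")
        ref_curve = np.asarray(aif_curve, dtype=float)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    t_inj = protocol.inject_time_s
    window = (t_inj, min(t_inj + window_s, float(t_s[-1])))
    cbv = compute_cbv(dr2s, ref_curve, t_s, window)
    cbf, _ = deconvolve_cbf(dr2s, ref_curve, t_s, svd_threshold)
    mtt, valid = compute_mtt(cbv, cbf)
    valid = valid & np.all(valid_sig, axis=-1)
    rel = relative_maps({"cbf": cbf, "cbv": cbv, "mtt": mtt}, contra_mask, valid)
    return HemodynamicMaps(
        cbf=cbf, cbv=cbv, mtt_s=mtt,
        rcbf=rel["rcbf"], rcbv=rel["rcbv"], rmtt=rel["rmtt"], valid=valid,
    )
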