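"""Lesion quantification and detectability statistics.

SUV layer: SUV = concentration (kBq/mL) x body weight (kg) / injected dose
(MBq), dimensionless under the 1 g/mL tissue-density convention.  Two lesion
metrics are computed inside a manually defined ROI: SUV_peak — the maximum,
over sphere centres inside the ROI, of the mean SUV within a 12-mm-diameter
sphere (the sphere itself may extend outside the ROI) — and SUV_max, the
maximum single voxel.  Percent changes between uncorrected (U) and
motion-corrected (MC) images use the uncorrected value as denominator; a
change is "considerable" when both metrics move by more than 5%.

Reader-score layer: readers mark suspected lesions on U and MC images and
grade each mark on the 4-point confidence scale chi (1 questionable ... 4
definite).  Marks are matched to the reference lesion set one-to-one by
distance; a matched mark is a true positive, an unmatched mark a false
positive, and an unmarked reference lesion a false negative scored chi = 0.
Delta-chi = chi(MC) - chi(U) per reader, and Delta-chi_1+2 sums the readers.
Significance: Wilcoxon signed rank for chi scores (exact enumeration for up
to 12 non-zero pairs), paired t for the SUV metrics; two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .grids import VoxelVolume

__all__ = ["suv_scale", "suv_peak", "suv_max", "delta_suv", "match_marks",
           "wilcoxon_signed_rank", "paired_t", "detection_summary",
           "DetectionStats"]


# ---------------------------------------------------------------------------
# SUV metrics
# ---------------------------------------------------------------------------

def suv_scale(volume: VoxelVolume, weight_kg: float,
              dose_MBq: float) -> VoxelVolume:
    """Convert an activity-concentration volume to SUV."""
    if weight_kg <= 0 or dose_MBq <= 0:
        raise ValueError("weight and dose must be > 0 (missing calibration?)")
    return VoxelVolume(volume.values * (weight_kg / dose_MBq),
                       volume.spacing, volume.origin, semantics="suv")


def _sphere_offsets(spacing, diameter_mm, ndim):
    """Index offsets of voxel centres within diameter/2 of the centre,
    C-ordered (deterministic summation order)."""
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing[:ndim]]
    axes = [np.arange(-h, h + 1) for h in half]
    mesh = np.meshgrid(*axes, indexing="ij")
    d2 = sum((m * s) ** 2 for m, s in zip(mesh, spacing))
    keep = d2 <= r ** 2
    return np.stack([m[keep] for m in mesh], axis=1)  # (n_off, ndim)


def suv_peak(volume: VoxelVolume, roi: np.ndarray,
             sphere_diameter_mm: float = 12.0) -> float:
    """Peak SUV: best sphere-mean over sphere centres inside the ROI.

    The sphere is discretised by voxel-centre inclusion; near the grid edge
    only in-grid voxels contribute to the mean.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.shape:
        raise ValueError("ROI must be on the volume grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    offsets = _sphere_offsets(volume.spacing, sphere_diameter_mm, volume.ndim)
    if any(2 * np.abs(offsets[:, a]).max() + 1 > volume.shape[a]
           for a in range(volume.ndim)):
        raise ValueError("sphere larger than the grid")
    centers = np.argwhere(roi)                        # (k, ndim)
    pos = centers[:, None, :] + offsets[None, :, :]   # (k, n_off, ndim)
    valid = np.ones(pos.shape[:2], dtype=bool)
    for a in range(volume.ndim):
        valid &= (pos[..., a] >= 0) & (pos[..., a] < volume.shape[a])
    flat = np.zeros(pos.shape[:2], dtype=np.int64)
    mult = 1
    for a in range(volume.ndim - 1, -1, -1):
        flat += pos[..., a].clip(0, volume.shape[a] - 1) * mult
        mult *= volume.shape[a]
    vals = volume.values.ravel()[flat]
    sums = np.where(valid, vals, 0.0).sum(axis=1)
    means = sums / valid.sum(axis=1)
    return float(means.max())


def suv_max(volume: VoxelVolume, roi: np.ndarray) -> float:
    """Maximum voxel value inside the ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(volume.values[roi].max())


def delta_suv(report_u: dict, report_mc: dict,
              considerable_pct: float = 5.0) -> pd.DataFrame:
    """Percent SUV changes MC vs U per lesion.

    ``report_u``/``report_mc`` map lesion id -> {"suv_peak": v, "suv_max": v}.
    Delta% = (MC - U) / U * 100; undefined (NaN, flagged) when U <= 0.  The
    "considerable" flag requires a change beyond ``considerable_pct`` in
    *both* metrics.
    """
    rows = []
    for lid in report_u:
        u, mc = report_u[lid], report_mc[lid]
        row = {"lesion": lid}
        undefined = False
        for metric in ("suv_peak", "suv_max"):
            uu, mm = float(u[metric]), float(mc[metric])
            row[f"{metric}_u"] = uu
            row[f"{metric}_mc"] = mm
            if uu > 0:
                row[f"delta_{metric}_pct"] = (mm - uu) / uu * 100.0
            else:
                row[f"delta_{metric}_pct"] = np.nan
                undefined = True
        row["delta_undefined"] = undefined
        if undefined:
            row["considerable"] = False
        else:
            dp, dm = row["delta_suv_peak_pct"], row["delta_suv_max_pct"]
            row["considerable"] = (abs(dp) > considerable_pct
                                   and abs(dm) > considerable_pct
                                   and np.sign(dp) == np.sign(dm))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reader-mark matching
# ---------------------------------------------------------------------------

def match_marks(marks: pd.DataFrame, reference: pd.DataFrame,
                tolerance_mm: float = 15.0) -> pd.DataFrame:
    """Match reader marks to reference lesions, label TP/FP, impute misses.

    ``marks`` columns: reader, mode (U|MC), z_mm, x_mm [, y_mm], score
    (chi in 1..4).  ``reference`` columns: lesion, z_mm, x_mm [, y_mm].
    Matching is one-to-one and greedy by distance within ``tolerance_mm``.
    Returns a tidy table with one row per (reader, mode, lesion-or-mark):
    TP rows carry the matched lesion id; FP rows lesion = None; unmarked
    reference lesions appear as false negatives with score 0.
    """
    axes = [c for c in ("z_mm", "x_mm", "y_mm") if c in reference.columns]
    out = []
    for (reader, mode), grp in marks.groupby(["reader", "mode"], sort=True):
        if grp.duplicated(subset=axes).any():
            pass  # coincident marks are legal; duplicates resolved by order
        ref_pos = reference[axes].to_numpy(dtype=float)
        mk_pos = grp[axes].to_numpy(dtype=float)
        dist = np.sqrt(((mk_pos[:, None, :] - ref_pos[None, :, :]) ** 2)
                       .sum(axis=2))
        pairs = sorted(((dist[i, j], i, j)
                        for i, j in product(range(len(grp)),
                                            range(len(reference)))
                        if dist[i, j] <= tolerance_mm))
        mark_match = {}
        taken = set()
        for d, i, j in pairs:
            if i in mark_match or j in taken:
                continue
            mark_match[i] = j
            taken.add(j)
        for i, (_, mk) in enumerate(grp.iterrows()):
            if i in mark_match:
                lid = reference.iloc[mark_match[i]]["lesion"]
                out.append(dict(reader=reader, mode=mode, lesion=lid,
                                score=int(mk["score"]), label="TP"))
            else:
                out.append(dict(reader=reader, mode=mode, lesion=None,
                                score=int(mk["score"]), label="FP"))
        for j, (_, ref) in enumerate(reference.iterrows()):
            if j not in taken:
                out.append(dict(reader=reader, mode=mode,
                                lesion=ref["lesion"], score=0, label="FN"))
    table = pd.DataFrame(out)
    dup = table[table["label"] != "FP"].duplicated(
        subset=["reader", "mode", "lesion"])
    if dup.any():
        raise ValueError("duplicate reader/mode rows for one lesion")
    return table


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(before, after, mode: str = "auto",
                         zero_method: str = "wilcox",
                         exact_limit: int = 12):
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zeros are dropped (``zero_method='wilcox'``, default) or kept in the
    ranking Pratt-style; ties get average ranks.  For up to ``exact_limit``
    non-zero pairs the p-value is exact, from full enumeration of the 2^m
    sign assignments; beyond that a normal approximation with tie and
    continuity corrections is used.

    Returns ``(W_plus, p)``.
    """
    d = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    if len(d) == 0:
        raise ValueError("empty sample")
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError(f"unknown zero method {zero_method!r}")
    if len(d) == 0 or np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
    w_plus = float(ranks[d > 0].sum())
    m = len(d)

    use_exact = (mode == "exact") or (mode == "auto" and m <= exact_limit)
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if use_exact:
        # distribution of W+ over all 2^m sign assignments (DP on 2*ranks,
        # which are integers even with average ranks)
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[:len(dist) - r].copy()
        dist /= 2.0 ** m
        w2 = int(np.rint(2 * w_plus))
        p_low = dist[:w2 + 1].sum()
        p_high = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        # normal approximation with tie correction, continuity correction
        # and an Edgeworth fourth-cumulant refinement (the null is symmetric
        # but platykurtic; the refinement matters for small m)
        mn = m * (m + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = (m * (m + 1) * (2 * m + 1) / 24.0
               - ((counts ** 3 - counts).sum()) / 48.0)
        sig = np.sqrt(var)
        g2 = (-(ranks ** 4).sum() / 8.0) / var ** 2  # excess kurtosis

        def cdf(x):
            z = (x - mn) / sig
            return (stats.norm.cdf(z)
                    - stats.norm.pdf(z) * (g2 / 24.0) * (z ** 3 - 3 * z))

        p_low = cdf(w_plus + 0.5)
        p_high = 1.0 - cdf(w_plus - 0.5)
        p = float(min(1.0, 2.0 * min(p_low, p_high)))
    return w_plus, float(p)


def paired_t(values_u, values_mc):
    """Classical two-sided paired t test; returns ``(t, p)``."""
    d = np.asarray(values_mc, dtype=float) - np.asarray(values_u, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Detection summary
# ---------------------------------------------------------------------------

@dataclass
class DetectionStats:
    tp_rate: pd.DataFrame        # per reader x mode + pooled
    fp_counts: pd.DataFrame      # per mode
    delta_chi: pd.DataFrame      # per lesion x reader
    delta_chi_sum: pd.Series     # Delta-chi_1+2 per lesion
    agree_increase: list         # lesions where all readers' delta > 0
    agree_decrease: list
    wilcoxon: tuple              # (W+, p) on paired chi scores


def detection_summary(matched: pd.DataFrame) -> DetectionStats:
    """Aggregate a matched score table into the detectability statistics."""
    ref = matched[matched["label"] != "FP"]
    readers = sorted(matched["reader"].unique())
    modes = ["U", "MC"]

    tp_rows = []
    for reader in readers:
        row = {"reader": reader}
        for mode in modes:
            sub = ref[(ref["reader"] == reader) & (ref["mode"] == mode)]
            row[mode] = (sub["label"] == "TP").mean() if len(sub) else np.nan
        tp_rows.append(row)
    pooled = {"reader": "pooled"}
    for mode in modes:
        pooled[mode] = np.mean([r[mode] for r in tp_rows])
    tp = pd.DataFrame(tp_rows + [pooled]).set_index("reader")

    fp = (matched[matched["label"] == "FP"]
          .groupby("mode").size().reindex(modes).fillna(0).astype(int))

    chi = (ref.pivot_table(index=["lesion", "reader"], columns="mode",
                           values="score", aggfunc="first")
           .reindex(columns=modes))
    delta = (chi["MC"] - chi["U"]).rename("delta_chi").reset_index()
    delta_sum = delta.groupby("lesion")["delta_chi"].sum()

    per_lesion = delta.pivot(index="lesion", columns="reader",
                             values="delta_chi")
    agree_up = per_lesion.index[(per_lesion > 0).all(axis=1)].tolist()
    agree_dn = per_lesion.index[(per_lesion < 0).all(axis=1)].tolist()

    wil = wilcoxon_signed_rank(chi["U"].to_numpy(), chi["MC"].to_numpy())
    return DetectionStats(tp_rate=tp, fp_counts=fp.to_frame("n_fp"),
                          delta_chi=delta, delta_chi_sum=delta_sum,
                          agree_increase=agree_up, agree_decrease=agree_dn,
                          wilcoxon=wil)
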