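"""Quantitative evaluation protocol: retrospective undersampling of
segmented references, metric computation on standardized crops, the
benchmark harness and the Friedman/Wilcoxon/Bonferroni statistics report."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from spiralcine.gridding import GriddedKSpace, SamplingMask
from spiralcine.stats import bonferroni, friedman_test, wilcoxon_signed_rank
from spiralcine.synthetic import CineImage

PSNR_CAP_DB = 99.0


@dataclass
class MetricRecord:
    method: str
    series_id: str
    ssim: float
    psnr: float
    nrmse: float

    def __post_init__(self):
        if not (-1.0 <= self.ssim <= 1.0):
            raise ValueError("ssim out of [-1, 1]")
        if self.nrmse < 0:
            raise ValueError("nrmse must be >= 0")


# ----------------------------------------------------------------------------
# retrospective undersampling
# ----------------------------------------------------------------------------


def retrospective_undersample(
    reference: GriddedKSpace, masks: SamplingMask
) -> GriddedKSpace:
    """Apply real-time sampling masks to fully binned reference k-space.

    Simulated frame f draws from reference phase ``f mod n_phases`` and is
    masked elementwise; the 7-arm variant is produced upstream by thinning
    the 13-arm schedule (every second arm) before mask generation.
    """
    if reference.grid_size != masks.mask.shape[-1]:
        raise ValueError("mask grid does not match reference grid")
    nph = reference.n_frames
    nf = masks.mask.shape[0]
    data = np.empty(
        (nf, reference.data.shape[1]) + reference.data.shape[2:], dtype=np.complex128
    )
    out_mask = np.empty((nf,) + masks.mask.shape[1:], dtype=np.uint8)
    for f in range(nf):
        p = f % nph
        m = masks.mask[f] * reference.mask[p]
        data[f] = reference.data[p] * m[None]
        out_mask[f] = m
    return GriddedKSpace(data=data, mask=out_mask)


# ----------------------------------------------------------------------------
# metric preparation and computation
# ----------------------------------------------------------------------------


def prepare_for_metrics(
    recon: CineImage | np.ndarray,
    reference: CineImage | np.ndarray,
    crop: int = 120,
    center: tuple | None = None,
) -> tuple:
    """Magnitude, centered crop, per-series min-max rescale to [0, 1]."""
    rec = np.abs(recon.data if isinstance(recon, CineImage) else np.asarray(recon))
    ref = np.abs(
        reference.data if isinstance(reference, CineImage) else np.asarray(reference)
    )
    if rec.shape != ref.shape:
        raise ValueError("recon and reference shapes differ")
    n = rec.shape[-1]
    if center is None:
        center = (rec.shape[-2] // 2, n // 2)
    cy, cx = int(center[0]), int(center[1])
    lo_y, lo_x = cy - crop // 2, cx - crop // 2
    if lo_y < 0 or lo_x < 0 or lo_y + crop > rec.shape[-2] or lo_x + crop > n:
        raise ValueError("crop does not fit inside the image")
    out = []
    for series in (rec, ref):
        c = series[..., lo_y : lo_y + crop, lo_x : lo_x + crop].astype(float)
        rng_ = c.max() - c.min()
        if rng_ <= 0:
            raise ValueError("constant series: zero data range")
        out.append((c - c.min()) / rng_)
    return out[0], out[1]


def compute_metrics(
    pair: tuple, method: str = "", series_id: str = ""
) -> MetricRecord:
    """SSIM / PSNR / NRMSE per frame, averaged over frames.

    Inputs must be prepared magnitude series on [0, 1]; PSNR of identical
    frames is reported as the 99 dB cap sentinel.
    """
    rec, ref = pair
    if np.any(~np.isfinite(rec)) or np.any(~np.isfinite(ref)):
        raise ValueError("NaN/Inf in metric inputs")
    ssims, psnrs, nrmses = [], [], []
    for f in range(rec.shape[0]):
        ssims.append(structural_similarity(ref[f], rec[f], data_range=1.0))
        mse = float(np.mean((rec[f] - ref[f]) ** 2))
        psnrs.append(PSNR_CAP_DB if mse == 0 else min(PSNR_CAP_DB, 10 * np.log10(1.0 / mse)))
        denom = float(np.linalg.norm(ref[f]))
        nrmses.append(float(np.linalg.norm(rec[f] - ref[f])) / max(denom, 1e-300))
    return MetricRecord(
        method=method,
        series_id=series_id,
        ssim=float(np.mean(ssims)),
        psnr=float(np.mean(psnrs)),
        nrmse=float(np.mean(nrmses)),
    )


# ----------------------------------------------------------------------------
# benchmark harness
# ----------------------------------------------------------------------------


def run_benchmark(
    cases: list,
    methods: dict,
    crop: int = 120,
    error_maps: bool = False,
) -> pd.DataFrame:
    """Full-factorial method x case benchmark.

    ``cases`` is a list of dicts with keys ``series_id``, ``y``
    (GriddedKSpace), ``A`` (MeasurementOperator), ``reference`` (CineImage)
    and optionally ``center``; ``methods`` maps method names to callables
    ``(y, A) -> ReconResult``.  Method failures are recorded per cell, not
    fatal.  Returns one MetricRecord row per (method, case).
    """
    rows = []
    emaps = {}
    for case in cases:
        for name, fn in methods.items():
            try:
                result = fn(case["y"], case["A"])
                pair = prepare_for_metrics(
                    result.x_hat,
                    case["reference"],
                    crop=crop,
                    center=case.get("center"),
                )
                rec = compute_metrics(pair, method=name, series_id=case["series_id"])
                row = asdict(rec)
                row["error"] = ""
                if error_maps:
                    emaps[(name, case["series_id"])] = np.abs(pair[0] - pair[1])
            except Exception as exc:  # pragma: no cover - failure path
                row = {
                    "method": name,
                    "series_id": case["series_id"],
                    "ssim": np.nan,
                    "psnr": np.nan,
                    "nrmse": np.nan,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            rows.append(row)
    df = pd.DataFrame(rows)
    if error_maps:
        df.attrs["error_maps"] = emaps
    return df


# ----------------------------------------------------------------------------
# statistics report
# ----------------------------------------------------------------------------


def _wide_table(df: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = df.pivot(index="series_id", columns="method", values=value)
    if wide.isna().any().any():
        missing = [
            f"({s}, {m})"
            for s in wide.index
            for m in wide.columns
            if pd.isna(wide.loc[s, m])
        ]
        raise ValueError("unbalanced design; missing cells: " + ", ".join(missing))
    return wide


def stats_compare(
    data: pd.DataFrame,
    value: str = "ssim",
    method: str = "auto",
) -> dict:
    """Friedman omnibus + pairwise Wilcoxon with Bonferroni correction.

    ``data`` is either a long table with columns (method, series_id,
    <value>) — e.g. the benchmark output — or a ratings table with columns
    (reader, method, subject, item, score), in which case reader scores are
    averaged and one report per item is returned.
    """
    if {"reader", "item", "score"}.issubset(data.columns):
        reports = {}
        avg = (
            data.groupby(["method", "subject", "item"])["score"]
            .mean()
            .reset_index()
            .rename(columns={"subject": "series_id", "score": "value"})
        )
        for item, sub in avg.groupby("item"):
            reports[item] = _stats_on_wide(_wide_table(sub, "value"), method)
        return reports
    return _stats_on_wide(_wide_table(data, value), method)


def _stats_on_wide(wide: pd.DataFrame, method: str) -> dict:
    methods_list = list(wide.columns)
    table = wide.to_numpy(dtype=float)
    omnibus = friedman_test(table, method=method)
    pairs = list(combinations(range(len(methods_list)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        res = wilcoxon_signed_rank(table[:, i], table[:, j])
        pairwise.append(
            {
                "pair": (methods_list[i], methods_list[j]),
                "statistic": res["statistic"],
                "pvalue": res["pvalue"],
                "pvalue_bonferroni": bonferroni(res["pvalue"], m),
            }
        )
    return {
        "methods": methods_list,
        "n_subjects": int(table.shape[0]),
        "friedman": omnibus,
        "pairwise": pairwise,
        "n_comparisons": m,
    }
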