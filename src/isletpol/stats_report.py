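"""Paired statistics and reporting over per-cell polarity records.

The scientific question is paired by construction: each cell contributes one
vascular and one avascular intensity, so face differences are tested with a
paired two-tailed Student's t test and summarised as mean +/- SEM (SD is also
reported, since with cell-to-cell spreads this large the two are easy to
confuse).  A blue-to-red heat-map LUT rendering of per-cell intensities is
included for visual inspection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from matplotlib import colormaps
from scipy import stats as sps

from .image_io import IntensityPlane
from .instance_seg import InstanceLabelMap, extract_boundaries

__all__ = ["PairedTestResult", "paired_t_test", "summarize_faces", "render_heatmap"]


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_diff: float
    t_stat: float
    df: int
    p_two_tailed: float
    mean_sem_a: tuple[float, float]
    mean_sem_b: tuple[float, float]
    degenerate: bool = False


def paired_t_test(a, b) -> PairedTestResult:
    """Paired two-tailed Student's t test on matched samples.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and the sample (n-1) standard
    deviation; p from the t distribution with n-1 degrees of freedom.  If all
    differences are identically zero the statistic is undefined and the result
    is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    mean_sem_a = (float(a.mean()), float(a.std(ddof=1) / np.sqrt(n)))
    mean_sem_b = (float(b.mean()), float(b.std(ddof=1) / np.sqrt(n)))
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(n, 0.0, np.nan, n - 1, np.nan, mean_sem_a, mean_sem_b, True)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTestResult(n, float(d.mean()), t, n - 1, 0.0, mean_sem_a, mean_sem_b)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTestResult(n, float(d.mean()), float(t), n - 1, float(p), mean_sem_a, mean_sem_b)


def _face_summary(values: np.ndarray) -> dict:
    n = values.size
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "sem": float(values.std(ddof=1) / np.sqrt(n)),
    }


def summarize_faces(records) -> dict:
    """Per-face summaries and paired tests over complete polarity records.

    ``records`` may be a list of :class:`~isletpol.polarity.PolarityRecord` or
    the equivalent DataFrame.  Records missing either face value are dropped
    listwise.  Returns a JSON-serialisable report; ``format_report`` renders
    the text version.
    """
    import pandas as pd

    from .polarity import records_to_dataframe

    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    complete = df.dropna(
        subset=["insulin_vascular", "insulin_avascular", "laminin_vascular", "laminin_avascular"]
    )
    if len(complete) < 2:
        raise ValueError("need at least 2 complete records")
    report: dict = {"n_cells": int(len(complete)), "n_dropped": int(len(df) - len(complete))}
    for channel in ("laminin", "insulin"):
        v = complete[f"{channel}_vascular"].to_numpy(float)
        a = complete[f"{channel}_avascular"].to_numpy(float)
        test = paired_t_test(v, a)
        report[channel] = {
            "vascular": _face_summary(v),
            "avascular": _face_summary(a),
            "vascular_avascular_ratio": float(v.mean() / a.mean()) if a.mean() != 0 else np.nan,
            "paired_t": asdict(test),
        }
    return report


def format_report(report: dict) -> str:
    lines = [f"n = {report['n_cells']} cell instances ({report['n_dropped']} dropped)"]
    for channel in ("laminin", "insulin"):
        ch = report[channel]
        for face in ("vascular", "avascular"):
            s = ch[face]
            lines.append(
                f"{channel} {face}: {s['mean']:.2f} +/- {s['sem']:.2f} SEM (SD {s['sd']:.2f})"
            )
        t = ch["paired_t"]
        lines.append(
            f"{channel} paired t({t['df']}) = {t['t_stat']:.3f}, p = {t['p_two_tailed']:.3g}"
        )
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def render_heatmap(
    channel,
    lm: InstanceLabelMap,
    mode: str = "cells",
    background=None,
) -> np.ndarray:
    """Blue-to-red LUT rendering of in-cell (or boundary) intensities.

    Intensities within the selected pixels are min-max normalised and mapped
    through a blue (low) to red (high) LUT; all other pixels show the optional
    greyscale ``background`` channel (or black).  Returns an (H, W, 3) uint8
    RGB image.
    """
    if mode not in ("cells", "boundaries"):
        raise ValueError("mode must be 'cells' or 'boundaries'")
    px = channel.pixels if isinstance(channel, IntensityPlane) else np.asarray(channel)
    px = px.astype(float)
    sel = lm.labels > 0 if mode == "cells" else extract_boundaries(lm).astype(bool)
    out = np.zeros(px.shape + (3,), dtype=np.uint8)
    if background is not None:
        bg = background.pixels if isinstance(background, IntensityPlane) else np.asarray(background)
        out[:] = bg.astype(np.uint8)[..., None]
    if sel.any():
        vals = px[sel]
        lo, hi = vals.min(), vals.max()
        norm = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo)
        rgba = colormaps["jet"](norm)
        out[sel] = np.clip(np.rint(rgba[:, :3] * 255), 0, 255).astype(np.uint8)
    return out
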