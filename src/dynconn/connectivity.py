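"""Static and tapered sliding-window functional connectivity.

Static connectivity is the Pearson correlation between component time
courses over the whole series, Fisher-z transformed.  Dynamic connectivity
slides a tapered window (rectangle of 22 TR convolved with a Gaussian of
sigma 3 TR, unit-sum) in steps of 1 TR, giving W = T - L windowed z-matrices
(193 for T = 215, L = 22), from which per-edge temporal variance is
computed.  Network-level summaries average edges within 7 x 7 network
blocks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ConnMatrix, EdgeVarianceMatrix, TimecourseSet, WindowStack

__all__ = [
    "fisher_z",
    "static_fc",
    "make_window_weights",
    "windowed_fc",
    "edge_variance",
    "network_block_means",
]

logger = logging.getLogger(__name__)

#: Clip bound applied to r before atanh, keeping z finite for |r| = 1.
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z = atanh(r) with r clipped to +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _zero_degenerate(corr: np.ndarray, variances: np.ndarray, context: str) -> np.ndarray:
    """Zero out rows/cols of zero-variance components; NaN-safe."""
    bad = ~(variances > 0)
    if bad.any() or np.isnan(corr).any():
        corr = np.nan_to_num(corr, nan=0.0)
        corr[bad, :] = 0.0
        corr[:, bad] = 0.0
        logger.warning(
            "%s: %d zero-variance component(s); their edges set to 0",
            context, int(bad.sum()),
        )
    return corr


def static_fc(ts: TimecourseSet) -> ConnMatrix:
    """Full-series Pearson correlation matrix, Fisher-z transformed.

    Constant components get all their edges set to 0 (with a warning) rather
    than aborting the run.
    """
    if ts.n_timepoints < 3:
        raise ValueError("static connectivity requires T >= 3")
    data = ts.data
    variances = data.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = _zero_degenerate(corr, variances, f"static_fc[{ts.subject_id}]")
    z = fisher_z(corr)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    return ConnMatrix(values=z, scale="fisher_z", component_ids=ts.component_ids)


def make_window_weights(window_length: int = 22, sigma: float = 3.0) -> np.ndarray:
    """Tapered window weights: rectangle convolved with a Gaussian kernel.

    The rectangle of width ``window_length`` is convolved with a Gaussian of
    standard deviation ``sigma`` TR (support +/- 3 sigma), the result is
    truncated to its central ``window_length`` samples and normalized to unit
    sum.  The taper is symmetric and monotone toward the edges; as
    sigma -> 0 it reduces to the uniform window.
    """
    if window_length < 3:
        raise ValueError("window_length must be >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(window_length), kernel, mode="full")
    start = (full.size - window_length) // 2
    w = full[start:start + window_length]
    w = 0.5 * (w + w[::-1])  # enforce exact symmetry against fp drift
    return w / w.sum()


def windowed_fc(
    ts: TimecourseSet,
    weights: np.ndarray,
    step: int = 1,
    sigma_tr: float = float("nan"),
) -> WindowStack:
    """Tapered sliding-window connectivity stack (Fisher z).

    Window onsets run 0, step, 2*step, ... up to T - L - 1 inclusive, so with
    step 1 the stack holds W = T - L windows (193 for the default T = 215,
    L = 22).  Within each window the correlation is the weighted Pearson
    correlation under the taper; zero-variance edges are set to 0 and logged.
    """
    weights = np.asarray(weights, dtype=float)
    length = weights.size
    t = ts.n_timepoints
    if t <= length:
        raise ValueError("need T > window length")
    if step < 1:
        raise ValueError("step must be >= 1")
    onsets = np.arange(0, t - length, step)
    # (W, C, L) strided view: no copy until the einsum
    segs = np.lib.stride_tricks.sliding_window_view(
        ts.data, length, axis=0
    )[onsets]
    mu = segs @ weights                       # (W, C) weighted means
    xc = segs - mu[:, :, None]
    cov = np.einsum("wcl,l,wdl->wcd", xc, weights, xc, optimize=True)
    var = np.einsum("wcc->wc", cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(var[:, :, None] * var[:, None, :])
        corr = cov / denom
    degenerate = ~(var > 0)
    if degenerate.any() or np.isnan(corr).any():
        corr = np.nan_to_num(corr, nan=0.0)
        bad_w, bad_c = np.nonzero(degenerate)
        corr[bad_w, bad_c, :] = 0.0
        corr[bad_w, :, bad_c] = 0.0
        logger.warning(
            "windowed_fc[%s]: %d degenerate (zero-variance) component-window "
            "pairs; their edges set to 0", ts.subject_id, bad_w.size,
        )
    stack = fisher_z(corr)
    di = np.arange(ts.n_components)
    stack[:, di, di] = 0.0
    stack = 0.5 * (stack + stack.transpose(0, 2, 1))
    return WindowStack(
        windows=stack,
        window_length_tr=length,
        sigma_tr=float(sigma_tr),
        step_tr=step,
        onsets=onsets,
        component_ids=list(ts.component_ids),
        subject_id=ts.subject_id,
    )


def edge_variance(stack: WindowStack) -> EdgeVarianceMatrix:
    """Per-edge sample variance (ddof=1) of z across windows; zero diagonal."""
    if stack.n_windows < 2:
        raise ValueError("edge variance requires at least 2 windows")
    var = stack.windows.var(axis=0, ddof=1)
    np.fill_diagonal(var, 0.0)
    var = np.maximum(0.5 * (var + var.T), 0.0)
    return EdgeVarianceMatrix(values=var, component_ids=list(stack.component_ids))


def network_block_means(
    values: np.ndarray | ConnMatrix | EdgeVarianceMatrix,
    partition: np.ndarray,
    networks: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean edge value per network block (7 x 7 for the default partition).

    Diagonal blocks average within-network off-diagonal edges only; the
    matrix diagonal never contributes.  Single-component diagonal blocks
    have no edges and come back NaN.
    """
    if isinstance(values, (ConnMatrix, EdgeVarianceMatrix)):
        values = values.values
    values = np.asarray(values, dtype=float)
    partition = np.asarray(partition)
    if partition.size != values.shape[0]:
        raise ValueError("partition must cover all components")
    if networks is None:
        seen = []
        for lab in partition:
            if lab not in seen:
                seen.append(lab)
        networks = tuple(seen)
    n = len(networks)
    out = np.full((n, n), np.nan)
    offdiag = ~np.eye(values.shape[0], dtype=bool)
    for a in range(n):
        ma = partition == networks[a]
        for b in range(a, n):
            mb = partition == networks[b]
            block = np.outer(ma, mb) & offdiag
            if block.any():
                out[a, b] = out[b, a] = values[block].mean()
    return pd.DataFrame(out, index=list(networks), columns=list(networks))
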