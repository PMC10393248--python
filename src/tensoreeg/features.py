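"""Nonlinear dynamical measures per (channel, band) sub-signal.

Twelve measures are computed from each band-limited series: sample
entropy (SampE), correlation dimension (CD), detrended fluctuation
analysis (DFA), seven recurrence-plot measures (RR, DET, LAM, TT, Lentr,
Lmax, Lmean) and two vertical-line recurrence measures (VertEnt,
AvgVertWhiteLen).  Recurrence plots use time-delay embedding with a
threshold chosen by quantile so the attained recurrence rate matches a
fixed target (default RR = 0.05, embedding dimension 10).

Lower sample entropy / higher determinism indicate a more regular,
predictable signal; the DFA exponent indexes long-range temporal
correlation (0.5 for white noise, 1.5 for Brownian motion); the
correlation dimension estimates the dimensionality of the underlying
attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from tensoreeg.bands import BAND_NAMES, BandSignals

#: the 12 measure names, in canonical tensor-axis order
MEASURE_NAMES = (
    "SampE", "CD", "DFA",
    "RR", "DET", "LAM", "TT", "Lentr", "Lmax", "Lmean",
    "VertEnt", "AvgVertWhiteLen",
)


class DegenerateSeriesError(ValueError):
    """Raised when a measure is undefined on the given series (e.g. constant)."""


@dataclass
class EmbeddingConfig:
    """Time-delay embedding and recurrence-plot parameters.

    recurrence_rate is the target fraction of recurrent off-diagonal
    pairs; theiler is the half-width of the temporal exclusion band
    around the line of identity (1 excludes the LOI only); lmin / vmin
    are the minimal diagonal / vertical line lengths entering the
    line-based measures.
    """

    emb_dim: int = 10
    delay: int = 1
    recurrence_rate: float = 0.05
    norm: str = "euclidean"
    theiler: int = 1
    lmin: int = 2
    vmin: int = 2

    def __post_init__(self) -> None:
        if self.emb_dim < 1 or self.delay < 1:
            raise ValueError("emb_dim and delay must be >= 1")
        if not 0 < self.recurrence_rate < 1:
            raise ValueError("recurrence_rate must lie in (0, 1)")
        if self.lmin < 2 or self.vmin < 2:
            raise ValueError("lmin and vmin must be >= 2")


@dataclass
class FeatureConfig:
    """Full per-measure configuration used by :func:`extract_features`."""

    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    cd_emb_dim: int = 10
    cd_delay: int = 1
    dfa_min_box: int = 4
    dfa_order: int = 1
    #: cap on embedded points for SampE / CD / recurrence analysis; longer
    #: series are truncated (not decimated, which would break line structure)
    max_points: int = 2000


@dataclass
class RecurrencePlot:
    """Thresholded binary recurrence matrix with its embedding provenance."""

    matrix: np.ndarray  # boolean, symmetric, True on the LOI
    epsilon: float
    attained_rr: float
    config: EmbeddingConfig


def embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: rows are (x_t, x_{t+tau}, ..., x_{t+(m-1)tau})."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for the requested embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


# ---------------------------------------------------------------------------
# sample entropy


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: -ln(A/B) with template matching at lengths m and m+1.

    Tolerance r = r_frac * SD(x); matches use the Chebyshev distance with
    the <= r convention and self-matches excluded.  Both counts use the
    N - m templates that admit an (m+1)-point continuation, so A/B is the
    conditional probability that sequences close for m points remain close
    for m + 1.

    Returns 0 for a constant series (all templates match at both lengths),
    ``inf`` when no (m+1)-matches exist, and ``nan`` when no m-matches
    exist (undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    r = r_frac * float(np.std(x))
    n_t = n - m  # templates that admit an (m+1)-point continuation
    # chebyshev distance accumulated coordinate by coordinate over full
    # n_t x n_t matrices; symmetric, so pair counts halve the off-diagonal
    d_m = np.zeros((n_t, n_t))
    for k in range(m):
        np.maximum(d_m, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]), out=d_m)
    b = (int(np.count_nonzero(d_m <= r)) - n_t) // 2
    np.maximum(d_m, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]), out=d_m)
    a = (int(np.count_nonzero(d_m <= r)) - n_t) // 2
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)


def correlation_sum(
    x: np.ndarray,
    radii: np.ndarray,
    emb_dim: int = 10,
    delay: int = 1,
    theiler: int = 1,
) -> np.ndarray:
    """C(r): fraction of embedded point pairs (|i-j| >= theiler) within r."""
    pts = embed(x, emb_dim, delay)
    d = pdist(pts)
    if theiler > 1:
        n = pts.shape[0]
        iu = np.triu_indices(n, k=1)
        d = d[(iu[1] - iu[0]) >= theiler]
    d = np.sort(d)
    return np.searchsorted(d, radii, side="right") / len(d)


def correlation_dimension(
    x: np.ndarray,
    emb_dim: int = 10,
    delay: int = 1,
    theiler: int = 1,
    n_radii: int = 16,
) -> float:
    """Grassberger-Procaccia correlation dimension.

    The correlation sum C(r) is evaluated over log-spaced radii between
    small and intermediate quantiles of the pairwise distance distribution
    and the dimension is the least-squares slope of log C vs log r over
    the scaling region (the radii window with the most stable local slope).
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.std(x) == 0:
        raise DegenerateSeriesError("correlation dimension undefined for a constant series")
    pts = embed(x, emb_dim, delay)
    d = pdist(pts)
    if theiler > 1:
        n = pts.shape[0]
        iu = np.triu_indices(n, k=1)
        d = d[(iu[1] - iu[0]) >= theiler]
    d = d[d > 0]
    if len(d) < 100:
        raise ValueError("too few distinct pairwise distances for a GP fit")
    lo, hi = np.quantile(d, [0.005, 0.5])
    radii = np.geomspace(max(lo, 1e-12), hi, n_radii)
    d_sorted = np.sort(d)
    c = np.searchsorted(d_sorted, radii, side="right") / len(d_sorted)
    valid = c > 0
    logr, logc = np.log(radii[valid]), np.log(c[valid])
    if len(logr) < 4:
        raise ValueError("correlation sum vanished over the radius range")
    # local slopes; pick the contiguous half-window with minimal slope spread
    slopes = np.diff(logc) / np.diff(logr)
    w = max(3, len(slopes) // 2)
    spreads = [np.std(slopes[i : i + w]) for i in range(len(slopes) - w + 1)]
    i0 = int(np.argmin(spreads))
    sel = slice(i0, i0 + w + 1)
    slope = np.polyfit(logr[sel], logc[sel], 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def dfa(
    x: np.ndarray,
    min_box: int = 4,
    max_box: int | None = None,
    order: int = 1,
    n_boxes: int = 16,
) -> float:
    """DFA scaling exponent alpha.

    The integrated, mean-removed profile is divided into non-overlapping
    windows of each box size, a polynomial trend (default linear) is
    removed per window, and alpha is the least-squares slope of
    log RMS-fluctuation vs log box size over logarithmically spaced boxes.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if max_box is None:
        max_box = n // 4
    if n < 16 * min_box or max_box <= min_box:
        raise ValueError(f"series of length {n} too short for DFA (min_box={min_box})")
    profile = np.cumsum(x - np.mean(x))
    sizes = np.unique(np.geomspace(min_box, max_box, n_boxes).astype(int))
    flucts = []
    t_full = np.arange(n, dtype=float)
    for s in sizes:
        k = n // s
        seg = profile[: k * s].reshape(k, s)
        t = t_full[:s]
        # vectorized per-window polynomial detrending
        coefs = np.polynomial.polynomial.polyfit(t, seg.T, order)
        trend = np.polynomial.polynomial.polyval(t, coefs)
        resid = seg - trend
        flucts.append(np.sqrt(np.mean(resid**2)))
    alpha = np.polyfit(np.log(sizes), np.log(flucts), 1)[0]
    return float(alpha)


# ---------------------------------------------------------------------------
# recurrence plots and their quantification


def recurrence_matrix(x: np.ndarray, cfg: EmbeddingConfig | None = None) -> RecurrencePlot:
    """Recurrence plot with threshold fixed by the target recurrence rate.

    epsilon is the RR-quantile of the off-diagonal pairwise embedded
    distances, so the attained recurrence rate matches the target up to
    distance ties.  The matrix is boolean, symmetric, True on the line of
    identity; the LOI is excluded from the attained-RR computation.
    """
    cfg = cfg or EmbeddingConfig()
    x = np.asarray(x, dtype=float).ravel()
    pts = embed(x, cfg.emb_dim, cfg.delay)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("too few embedded points for a recurrence plot")
    d = pdist(pts, metric=cfg.norm)
    if np.all(d == 0):
        raise DegenerateSeriesError(
            "all embedded distances are zero; fixed-RR threshold undefined"
        )
    eps = float(np.quantile(d, cfg.recurrence_rate))
    rec = d <= eps
    attained = float(np.mean(rec))
    matrix = squareform(rec).astype(bool)
    np.fill_diagonal(matrix, True)
    return RecurrencePlot(matrix=matrix, epsilon=eps, attained_rr=attained, config=cfg)


def _runs_in_rows(rows: np.ndarray) -> np.ndarray:
    """Run lengths of True in each row of a 2-D boolean array, pooled.

    A single vectorized pass: a False separator column is appended so runs
    cannot bridge rows.
    """
    padded = np.zeros((rows.shape[0], rows.shape[1] + 1), dtype=np.int8)
    padded[:, :-1] = rows
    flat = np.concatenate(([0], padded.ravel()))
    edges = np.diff(flat)
    return np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)


def _diagonal_lengths(matrix: np.ndarray, theiler: int) -> np.ndarray:
    """Lengths of all diagonal recurrent lines outside the Theiler band.

    Both triangles are scanned (the plot is symmetric, so each structure
    is counted twice, as is conventional).
    """
    n = matrix.shape[0]
    # skew the matrix so diagonals become rows of a (2n-1) x n array
    skew = np.zeros((2 * n - 1, n), dtype=bool)
    for k in range(-(n - 1), n):
        if abs(k) < theiler:
            continue
        d = np.diagonal(matrix, offset=k)
        skew[k + n - 1, : d.shape[0]] = d
    return _runs_in_rows(skew)


def _vertical_lengths(matrix: np.ndarray, value: bool) -> np.ndarray:
    """Lengths of vertical runs of `value` over all columns (LOI included)."""
    cols = matrix.T if value else ~matrix.T
    return _runs_in_rows(cols)


def _entropy(lengths: np.ndarray) -> float:
    """Shannon entropy (natural log) of the length histogram."""
    if len(lengths) == 0:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def rqa_measures(rp: RecurrencePlot) -> dict[str, float]:
    """The seven recurrence-quantification measures of a plot.

    RR is the attained off-diagonal recurrence rate.  Diagonal-line
    measures (DET, Lentr, Lmax, Lmean) exclude the LOI / Theiler band;
    vertical-line measures (LAM, TT) scan full columns.  Empty line
    distributions yield 0 by convention.
    """
    cfg = rp.config
    m = rp.matrix
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_off = int(np.count_nonzero(m & off))

    diag_all = _diagonal_lengths(m, cfg.theiler)
    diag_long = diag_all[diag_all >= cfg.lmin]
    n_diag_points = int(diag_all.sum())
    det = float(diag_long.sum() / n_diag_points) if n_diag_points else 0.0

    vert_all = _vertical_lengths(m, value=True)
    vert_long = vert_all[vert_all >= cfg.vmin]
    n_vert_points = int(vert_all.sum())
    lam = float(vert_long.sum() / n_vert_points) if n_vert_points else 0.0
    tt = float(vert_long.mean()) if len(vert_long) else 0.0

    return {
        "RR": float(n_off / (n * (n - 1))) if n > 1 else 0.0,
        "DET": det,
        "LAM": lam,
        "TT": tt,
        "Lentr": _entropy(diag_long),
        "Lmax": float(diag_long.max()) if len(diag_long) else 0.0,
        "Lmean": float(diag_long.mean()) if len(diag_long) else 0.0,
    }


def vertical_line_measures(rp: RecurrencePlot) -> dict[str, float]:
    """Vertical-structure measures: VertEnt and AvgVertWhiteLen.

    VertEnt is the Shannon entropy (natural log) of the recurrent vertical
    line-length distribution (lengths >= vmin); AvgVertWhiteLen is the
    mean length of vertical runs of non-recurrent ("white") points.
    Empty distributions yield 0.
    """
    cfg = rp.config
    vert = _vertical_lengths(rp.matrix, value=True)
    vert = vert[vert >= cfg.vmin]
    white = _vertical_lengths(rp.matrix, value=False)
    return {
        "VertEnt": _entropy(vert),
        "AvgVertWhiteLen": float(white.mean()) if len(white) else 0.0,
    }


# ---------------------------------------------------------------------------
# per-recording feature extraction


def feature_vector(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """All 12 measures of one band-limited series.

    Raises :class:`DegenerateSeriesError` on constant input; embedding-based
    measures analyse at most ``cfg.max_points`` embedded points.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float).ravel()
    if np.std(x) == 0:
        raise DegenerateSeriesError("constant sub-signal; nonlinear measures undefined")
    emb = cfg.embedding
    n_keep = cfg.max_points + (emb.emb_dim - 1) * emb.delay
    x_emb = x[:n_keep]
    values = {
        "SampE": sample_entropy(x_emb[: cfg.max_points + cfg.sampen_m + 1],
                                m=cfg.sampen_m, r_frac=cfg.sampen_r_frac),
        "CD": correlation_dimension(x_emb, emb_dim=cfg.cd_emb_dim, delay=cfg.cd_delay),
        "DFA": dfa(x, min_box=cfg.dfa_min_box, order=cfg.dfa_order),
    }
    rp = recurrence_matrix(x_emb, emb)
    values.update(rqa_measures(rp))
    values.update(vertical_line_measures(rp))
    return values


def extract_features(
    band_signals: dict[str, BandSignals],
    cfg: FeatureConfig | None = None,
) -> tuple[dict[tuple[str, str], dict[str, float]], list[dict]]:
    """Compute the 12 measures per (channel, band) sub-signal.

    Parameters
    ----------
    band_signals : mapping channel label -> :class:`BandSignals`
    cfg : feature configuration

    Returns
    -------
    features : {(channel, band): {measure: value}}
    missing : list of {"channel", "band", "reason"} records for sub-signals
        on which a measure was undefined (degenerate input); such cells are
        reported as missing, never silently zeroed.
    """
    cfg = cfg or FeatureConfig()
    features: dict[tuple[str, str], dict[str, float]] = {}
    missing: list[dict] = []
    for channel, bs in band_signals.items():
        for band in bs.band_names:
            try:
                features[(channel, band)] = feature_vector(bs.bands[band], cfg)
            except (DegenerateSeriesError, ValueError) as exc:
                missing.append({"channel": channel, "band": band, "reason": str(exc)})
    return features, missing


def cohort_feature_table(
    recordings,
    cfg: FeatureConfig | None = None,
    wavelet: str = "db4",
) -> pd.DataFrame:
    """Long-format feature table for a list of recordings.

    Columns: participant, age_code, channel, band, measure, value.  Cells
    on which a measure was undefined are absent from the table (the
    tensor builder's complete-case rule then drops the participant).
    """
    cfg = cfg or FeatureConfig()
    from tensoreeg.bands import decompose_bands

    rows = []
    for rec in recordings:
        bands = {
            lab: decompose_bands(rec.data[i], rec.fs, wavelet=wavelet)
            for i, lab in enumerate(rec.channel_labels)
        }
        features, _missing = extract_features(bands, cfg)
        for (channel, band), vals in features.items():
            for measure, value in vals.items():
                if np.isfinite(value):
                    rows.append(
                        {
                            "participant": rec.participant_id,
                            "age_code": rec.age_code,
                            "channel": channel,
                            "band": band,
                            "measure": measure,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
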