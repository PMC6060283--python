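"""Ordinal-pattern distributions and permutation-entropy measures.

Permutation entropy (PE) quantifies the irregularity of a scalar time
series through the relative frequencies of the ordinal patterns (rank
orderings) of short embedding vectors.  For a series ``x(1..N)``, an
embedding dimension ``m`` and a delay ``lam``, the vectors

    X(i) = (x(i), x(i + lam), ..., x(i + (m-1) lam))

are each mapped to the permutation ``(j_1 .. j_m)`` that sorts them in
ascending order, ties broken by ascending position.  PE is the Shannon
entropy of the resulting pattern distribution, normalised by ``ln(m!)``
so that white noise scores close to 1 and a monotone trend scores 0.

Alongside the Shannon form, the Tsallis (TPE), Renyi (RPE) and
min-entropy (MPE) variants of order ``q`` are provided; all are
normalised to ``[0, 1]`` so the measures are directly comparable.

Features for the seizure-prediction pipeline are PE values computed per
channel on consecutive non-overlapping windows (default 5 s), the
standard compromise between temporal resolution and the local
stationarity the ordinal statistics assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError
from .signal_io import Recording

__all__ = [
    "EntropyConfig",
    "PatternDistribution",
    "FeatureSeries",
    "ordinal_pattern",
    "pattern_distribution",
    "permutation_entropy",
    "entropy_variant",
    "sliding_feature_matrix",
    "n_windows",
    "write_feature_series",
    "read_feature_series",
]

_MEASURES = ("PE", "TPE", "RPE", "MPE")


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the ordinal-entropy feature extractor.

    Parameters
    ----------
    m : int
        Embedding dimension (pattern length), 2..7.  Default 4.
    lam : int
        Embedding delay in samples.  Default 1.
    measure : str
        One of ``PE`` (Shannon), ``TPE`` (Tsallis), ``RPE`` (Renyi),
        ``MPE`` (min-entropy).
    q : float
        Entropic order for TPE/RPE (must differ from 1).  Default 2.
    window_len : float
        Sliding-window length in seconds (non-overlapping).  Default 5.
    overlap : float
        Fractional window overlap in [0, 1).  Default 0, matching the
        non-overlapping windows the pipeline uses throughout.
    """

    m: int = 4
    lam: int = 1
    measure: str = "PE"
    q: float = 2.0
    window_len: float = 5.0
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if not 2 <= self.m <= 7:
            raise ConfigurationError(f"embedding dimension m={self.m} outside 2..7")
        if self.lam < 1:
            raise ConfigurationError(f"delay lam={self.lam} must be >= 1")
        if self.measure not in _MEASURES:
            raise ConfigurationError(f"unknown measure {self.measure!r}; expected one of {_MEASURES}")
        if self.measure in ("TPE", "RPE") and self.q == 1:
            raise ConfigurationError("q must differ from 1 for TPE/RPE")
        if not 0 <= self.overlap < 1:
            raise ConfigurationError(f"overlap={self.overlap} outside [0, 1)")
        if self.window_len <= 0:
            raise ConfigurationError("window_len must be positive")


@dataclass
class PatternDistribution:
    """Counts of observed ordinal patterns.

    ``counts`` maps each observed pattern (a tuple of 1-based ranks,
    i.e. a permutation of ``1..m``) to its number of occurrences;
    ``n_vectors`` is the total number of embedding vectors, equal to
    ``N - (m-1)*lam`` for a series of length N.
    """

    counts: Dict[Tuple[int, ...], int]
    n_vectors: int

    def probabilities(self) -> np.ndarray:
        """Relative frequencies of the observed (distinct) patterns."""
        if self.n_vectors < 1:
            raise ValidationError("empty pattern distribution")
        return np.asarray(list(self.counts.values()), dtype=float) / self.n_vectors


@dataclass
class FeatureSeries:
    """Per-channel entropy per window, with the window -> time mapping.

    ``values`` has shape (n_channels, x) where x is the number of
    complete windows; ``window_starts`` gives each window's start time
    in seconds from the recording origin.
    """

    values: np.ndarray
    window_starts: np.ndarray
    config: EntropyConfig
    channel_ids: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def ordinal_pattern(v: np.ndarray) -> Tuple[int, ...]:
    """Map a length-m vector to its ordinal pattern (permutation of 1..m).

    The pattern is the index sequence (j_1..j_m), 1-based, such that
    v[j_1] <= ... <= v[j_m].  Equal elements keep ascending index order
    (stable sort), the conventional tie rule.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("ordinal_pattern expects a 1-D vector of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite element in embedding vector")
    return tuple(int(j) + 1 for j in np.argsort(v, kind="stable"))


def _embed(series: np.ndarray, m: int, lam: int) -> np.ndarray:
    """Return the (N-(m-1)lam, m) matrix of delay-embedding vectors."""
    n = series.size - (m - 1) * lam
    idx = np.arange(n)[:, None] + lam * np.arange(m)[None, :]
    return series[idx]


def _pattern_codes(series: np.ndarray, m: int, lam: int) -> np.ndarray:
    """Integer code of each embedding vector's ordinal pattern.

    Codes are the mixed-radix encoding of the stable argsort; two
    vectors share a code iff they share an ordinal pattern.
    """
    emb = _embed(series, m, lam)
    ranks = np.argsort(emb, axis=1, kind="stable")
    weights = m ** np.arange(m, dtype=np.int64)
    return ranks @ weights


def _decode(code: int, m: int) -> Tuple[int, ...]:
    out = []
    for _ in range(m):
        out.append(int(code % m) + 1)
        code //= m
    return tuple(out)


def pattern_distribution(series: np.ndarray, cfg: EntropyConfig) -> PatternDistribution:
    """Count ordinal patterns over all embedding vectors of ``series``."""
    series = np.asarray(series, dtype=float).ravel()
    m, lam = cfg.m, cfg.lam
    min_len = (m - 1) * lam + 1
    if series.size < min_len:
        raise ValidationError(
            f"series of length {series.size} too short for m={m}, lam={lam} (need >= {min_len})"
        )
    if not np.all(np.isfinite(series)):
        raise ValidationError("series contains non-finite values")
    codes = _pattern_codes(series, m, lam)
    uniq, cnt = np.unique(codes, return_counts=True)
    counts = {_decode(int(c), m): int(k) for c, k in zip(uniq, cnt)}
    return PatternDistribution(counts=counts, n_vectors=int(codes.size))


def permutation_entropy(dist: PatternDistribution, m: int) -> float:
    """Normalised Shannon permutation entropy of a pattern distribution.

    H = -sum(P_g ln P_g) / ln(m!), in [0, 1].
    """
    p = dist.probabilities()
    h = -float(np.sum(p * np.log(p)))
    return h / math.log(math.factorial(m))


def entropy_variant(dist: PatternDistribution, m: int, measure: str, q: float = 2.0) -> float:
    """Tsallis/Renyi/min-entropy variants, each normalised to [0, 1].

    RPE(q) = ln(sum P^q) / (1-q) / ln(m!);
    TPE(q) = (1 - sum P^q)/(q-1), divided by its value for the uniform
    distribution over all m! patterns, (1 - (m!)^(1-q))/(q-1);
    MPE = -ln(max P) / ln(m!)  (the q -> inf Renyi limit).
    """
    p = dist.probabilities()
    log_mfact = math.log(math.factorial(m))
    if measure == "PE":
        return permutation_entropy(dist, m)
    if measure == "MPE":
        return -math.log(float(np.max(p))) / log_mfact
    if q == 1:
        raise ConfigurationError("q must differ from 1 for TPE/RPE")
    s = float(np.sum(p**q))
    if measure == "RPE":
        return math.log(s) / (1.0 - q) / log_mfact
    if measure == "TPE":
        norm = (1.0 - math.factorial(m) ** (1.0 - q)) / (q - 1.0)
        return (1.0 - s) / (q - 1.0) / norm
    raise ConfigurationError(f"unknown measure {measure!r}")


def _window_entropies(windows: np.ndarray, cfg: EntropyConfig) -> np.ndarray:
    """Entropy of each row of a (x, win_samples) matrix of windows."""
    m, lam = cfg.m, cfg.lam
    x, w = windows.shape
    n_vec = w - (m - 1) * lam
    # Pattern codes for all windows at once, then a per-row histogram.
    emb = windows[:, np.arange(n_vec)[:, None] + lam * np.arange(m)[None, :]]
    ranks = np.argsort(emb, axis=2, kind="stable")
    weights = m ** np.arange(m, dtype=np.int64)
    codes = ranks @ weights
    log_mfact = math.log(math.factorial(m))
    out = np.empty(x, dtype=float)
    for i in range(x):
        cnt = np.bincount(codes[i])
        p = cnt[cnt > 0] / n_vec
        if cfg.measure == "PE":
            out[i] = -np.sum(p * np.log(p)) / log_mfact
        elif cfg.measure == "MPE":
            out[i] = -math.log(float(p.max())) / log_mfact
        elif cfg.measure == "RPE":
            out[i] = math.log(float(np.sum(p**cfg.q))) / (1.0 - cfg.q) / log_mfact
        else:  # TPE
            norm = (1.0 - math.factorial(m) ** (1.0 - cfg.q)) / (cfg.q - 1.0)
            out[i] = (1.0 - float(np.sum(p**cfg.q))) / (cfg.q - 1.0) / norm
    return out


def n_windows(L: int, fs: float, window_len: float) -> int:
    """Number of complete non-overlapping windows: floor(L / (window_len * fs))."""
    if L < 0:
        raise ValidationError("L must be non-negative")
    return int(L // round(window_len * fs))


def sliding_feature_matrix(rec: Recording, cfg: EntropyConfig) -> FeatureSeries:
    """Entropy per channel on consecutive non-overlapping windows.

    Each channel is processed independently; a trailing partial window
    is discarded.  Overlapping windows (cfg.overlap > 0) step by
    ``window_len * (1 - overlap)`` seconds.
    """
    win = int(round(cfg.window_len * rec.fs))
    if rec.n_samples < win:
        raise ValidationError(
            f"recording of {rec.n_samples} samples shorter than one {cfg.window_len}-s window"
        )
    if cfg.overlap == 0:
        x = rec.n_samples // win
        starts = np.arange(x) * win
    else:
        step = max(1, int(round(win * (1 - cfg.overlap))))
        starts = np.arange(0, rec.n_samples - win + 1, step)
        x = starts.size
    values = np.empty((rec.n_channels, x), dtype=float)
    for c in range(rec.n_channels):
        windows = rec.signal[c][starts[:, None] + np.arange(win)[None, :]]
        values[c] = _window_entropies(windows, cfg)
    return FeatureSeries(
        values=values,
        window_starts=starts / rec.fs,
        config=cfg,
        channel_ids=list(rec.channel_ids),
    )


def write_feature_series(fs: FeatureSeries, path) -> None:
    """Write a feature series as a delimited table, config in a header comment."""
    cfg = fs.config
    header = (
        f"# m={cfg.m} lam={cfg.lam} measure={cfg.measure} q={cfg.q} "
        f"window_len={cfg.window_len} overlap={cfg.overlap}\n"
        "window_start_s\t" + "\t".join(fs.channel_ids or [f"ch{i}" for i in range(fs.n_channels)])
    )
    table = np.column_stack([fs.window_starts, fs.values.T])
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_feature_series(path) -> FeatureSeries:
    """Read a feature series written by :func:`write_feature_series`."""
    with open(path) as fh:
        meta_line = fh.readline().strip().lstrip("# ")
        cols = fh.readline().strip().split("\t")
    meta = dict(item.split("=") for item in meta_line.split())
    cfg = EntropyConfig(
        m=int(meta["m"]),
        lam=int(meta["lam"]),
        measure=meta["measure"],
        q=float(meta["q"]),
        window_len=float(meta["window_len"]),
        overlap=float(meta["overlap"]),
    )
    table = np.loadtxt(path, delimiter="\t", skiprows=2, ndmin=2)
    return FeatureSeries(
        values=table[:, 1:].T, window_starts=table[:, 0], config=cfg, channel_ids=cols[1:]
    )


def with_measure(cfg: EntropyConfig, measure: str, q: float | None = None) -> EntropyConfig:
    """Copy of ``cfg`` with a different entropy measure (and optionally q)."""
    return replace(cfg, measure=measure, q=cfg.q if q is None else q)
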