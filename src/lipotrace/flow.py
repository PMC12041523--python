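"""Dye-dilution proliferation metrics and MFI normalization.

A proliferation dye (e.g. CellTrace Violet) is halved at each cell division,
so acquired events form log2-spaced peaks in log10 intensity: generation ``i``
sits at ``mu0 - i * log10(2)``.  :class:`DyeDilutionModel` fits a 1-D Gaussian
mixture with those fixed centers, a shared width, and free weights by
expectation-maximization; :class:`DyeDilutionResults` carries the expected
per-generation counts and the two derived population metrics:

* percent divided — share of acquired cells beyond generation 0,
  ``100 * sum_{i>=1} n_i / sum_i n_i``;
* division index — mean number of divisions per *precursor* cell; with
  precursor counts ``P_i = n_i / 2**i`` it is ``sum i*P_i / sum P_i``.

MFI normalization to a reference sample and the stimulated/unstimulated
fold-change are provided as plain functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

_LOG10_2 = np.log10(2.0)
_SIGMA_FLOOR = 1e-4


class GenerationFitError(RuntimeError):
    """EM failed to converge within the iteration budget."""


@dataclass
class GenerationModelConfig:
    """Settings of the generation mixture.

    ``mu0_source`` fixes how the undivided-peak position is resolved:
    ``"fixed"`` (use ``mu0``), ``"unstimulated_control_mode"`` (mode of a
    matched unstimulated control passed to ``fit``), or ``"rightmost_peak"``
    (rightmost histogram peak of the fitted sample itself).
    """

    max_generations: int = 8
    delta: float = _LOG10_2  # log10 spacing per division (2-fold dilution)
    sigma: float = 0.05  # initial / fixed shared peak width (log10 units)
    fix_sigma: bool = False
    mu0_source: str = "rightmost_peak"
    mu0: float | None = None
    autofluorescence_floor: float = 0.0
    max_iter: int = 1000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.mu0_source not in (
            "fixed",
            "unstimulated_control_mode",
            "rightmost_peak",
        ):
            raise ValueError(f"unknown mu0_source {self.mu0_source!r}")
        if self.mu0_source == "fixed" and self.mu0 is None:
            raise ValueError("mu0 required when mu0_source='fixed'")


@dataclass
class GenerationProfile:
    """Per-generation expected event counts and the fitted peak parameters."""

    counts: np.ndarray  # n_i, i = 0..G
    mu0: float
    sigma: float
    delta: float = _LOG10_2
    assignment: str = "soft"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("generation counts must be non-negative")


def _histogram_mode(x: np.ndarray, bin_width: float = 0.02) -> float:
    """Mode of a 1-D sample from a smoothed histogram."""
    lo, hi = x.min(), x.max()
    if hi - lo < bin_width:
        return float(np.median(x))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[np.argmax(smooth)])


def _rightmost_peak(x: np.ndarray, bin_width: float = 0.02) -> float:
    """Rightmost local maximum of a smoothed histogram (>= 5% of global max)."""
    lo, hi = x.min(), x.max()
    if hi - lo < bin_width:
        return float(np.median(x))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    floor = 0.05 * smooth.max()
    peaks = [
        i
        for i in range(len(smooth))
        if smooth[i] >= floor
        and (i == 0 or smooth[i] >= smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] > smooth[i + 1])
    ]
    return float(centers[peaks[-1]]) if peaks else float(centers[np.argmax(smooth)])


class DyeDilutionModel:
    """Gaussian mixture over log10 dye intensity with log2-spaced centers.

    Parameters
    ----------
    events
        Event table (``DataFrame``) or 1-D array of raw intensities.
    channel
        Column holding the dye intensity when ``events`` is a DataFrame.
    config
        :class:`GenerationModelConfig`; defaults are 8 generations, 2-fold
        spacing, shared width fitted by EM.
    """

    def __init__(
        self,
        events,
        channel: str = "ctv",
        config: GenerationModelConfig | None = None,
    ) -> None:
        if isinstance(events, pd.DataFrame):
            values = events[channel].to_numpy(dtype=float)
        else:
            values = np.asarray(events, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("event intensities must be finite")
        values = values - (config.autofluorescence_floor if config else 0.0)
        keep = values > 0
        if keep.sum() < len(values):
            warnings.warn(
                f"dropping {len(values) - keep.sum()} non-positive events",
                stacklevel=2,
            )
        self.log10_intensity = np.log10(values[keep])
        if len(self.log10_intensity) < 200:
            raise ValueError("need at least 200 events to fit generations")
        self.config = config or GenerationModelConfig()

    def _resolve_mu0(self, control) -> float:
        cfg = self.config
        if cfg.mu0_source == "fixed":
            return float(cfg.mu0)
        if cfg.mu0_source == "unstimulated_control_mode":
            if control is None:
                raise ValueError(
                    "mu0_source='unstimulated_control_mode' requires a control sample"
                )
            ctrl = np.asarray(control, dtype=float)
            ctrl = np.log10(ctrl[ctrl > 0])
            return _histogram_mode(ctrl)
        return _rightmost_peak(self.log10_intensity)

    def fit(self, control=None) -> "DyeDilutionResults":
        """Run EM.  ``control`` is the raw-intensity unstimulated sample used
        when ``mu0_source='unstimulated_control_mode'``."""
        cfg = self.config
        x = self.log10_intensity
        mu0 = self._resolve_mu0(control)
        G = cfg.max_generations
        centers = mu0 - cfg.delta * np.arange(G + 1)

        if cfg.autofluorescence_floor > 0 and 10.0 ** centers[-1] < 10.0 * (
            cfg.autofluorescence_floor
        ):
            warnings.warn(
                "dimmest generation approaches the autofluorescence floor; "
                "counts beyond it are truncated",
                stacklevel=2,
            )

        # initialize weights from histogram mass within delta/2 of each center
        d2 = (x[:, None] - centers[None, :]) ** 2
        nearest = np.argmin(d2, axis=1)
        within = np.abs(x - centers[nearest]) <= cfg.delta / 2
        w = np.bincount(nearest[within], minlength=G + 1).astype(float)
        w = (w + 1e-6) / (w + 1e-6).sum()
        sigma = max(cfg.sigma, _SIGMA_FLOOR)

        n = len(x)
        converged = False
        loglik = -np.inf
        for it in range(1, cfg.max_iter + 1):
            # E step in log space for numerical safety at small sigma
            logp = (
                np.log(np.clip(w, 1e-300, None))[None, :]
                - 0.5 * d2 / sigma**2
                - np.log(sigma)
                - 0.5 * np.log(2 * np.pi)
            )
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            resp = np.exp(logp - lse[:, None])
            loglik = float(lse.sum())

            w_new = resp.mean(axis=0)
            if cfg.fix_sigma:
                sigma_new = sigma
            else:
                sigma_new = max(
                    float(np.sqrt((resp * d2).sum() / n)), _SIGMA_FLOOR
                )
            if (
                np.max(np.abs(w_new - w)) < cfg.tol
                and abs(sigma_new - sigma) < cfg.tol
            ):
                w, sigma = w_new, sigma_new
                converged = True
                break
            w, sigma = w_new, sigma_new
        if not converged:
            raise GenerationFitError(
                f"EM did not converge in {cfg.max_iter} iterations "
                f"(loglik={loglik:.3f}, sigma={sigma:.4f})"
            )

        counts = w * n
        return DyeDilutionResults(
            model=self,
            counts=counts,
            responsibilities=resp,
            mu0=mu0,
            sigma=sigma,
            loglik=loglik,
            n_iter=it,
        )


@dataclass
class DyeDilutionResults:
    """Fitted generation weights, counts, and the derived metrics."""

    model: DyeDilutionModel
    counts: np.ndarray
    responsibilities: np.ndarray
    mu0: float
    sigma: float
    loglik: float
    n_iter: int

    @property
    def n_events(self) -> int:
        return len(self.model.log10_intensity)

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def profile(self, assignment: str = "soft") -> GenerationProfile:
        """Per-generation counts; ``assignment`` is 'soft' (expected counts,
        default) or 'hard' (argmax responsibilities)."""
        if assignment == "soft":
            counts = self.counts
        elif assignment == "hard":
            counts = np.bincount(
                np.argmax(self.responsibilities, axis=1),
                minlength=len(self.counts),
            ).astype(float)
        else:
            raise ValueError("assignment must be 'soft' or 'hard'")
        return GenerationProfile(
            counts=counts,
            mu0=self.mu0,
            sigma=self.sigma,
            delta=self.model.config.delta,
            assignment=assignment,
        )

    @property
    def percent_divided(self) -> float:
        return percent_divided(self.profile())

    @property
    def division_index(self) -> float:
        return division_index(self.profile())

    def summary(self) -> str:
        lines = [
            "Dye-dilution generation model",
            "=" * 45,
            f"events          {self.n_events}",
            f"mu0 (log10)     {self.mu0:.4f}",
            f"sigma (log10)   {self.sigma:.4f}",
            f"EM iterations   {self.n_iter}",
            f"log-likelihood  {self.loglik:.2f}",
            "-" * 45,
            f"{'gen':>4} {'count':>12} {'fraction':>10}",
        ]
        frac = self.fractions
        for i, (c, f) in enumerate(zip(self.counts, frac)):
            lines.append(f"{i:>4} {c:>12.1f} {f:>10.4f}")
        lines.append("-" * 45)
        lines.append(f"percent divided  {self.percent_divided:.1f}%")
        lines.append(f"division index   {self.division_index:.3f}")
        return "\n".join(lines)


def fit_generations(
    events,
    channel: str = "ctv",
    config: GenerationModelConfig | None = None,
    control=None,
) -> GenerationProfile:
    """Fit the generation mixture and return the per-generation profile."""
    return DyeDilutionModel(events, channel, config).fit(control).profile()


def _counts(profile) -> np.ndarray:
    counts = np.asarray(
        profile.counts if hasattr(profile, "counts") else profile, dtype=float
    )
    if counts.sum() <= 0:
        raise ValueError("profile has no events")
    return counts


def percent_divided(profile) -> float:
    """Percentage of acquired cells beyond the undivided generation."""
    counts = _counts(profile)
    return float(100.0 * counts[1:].sum() / counts.sum())


def division_index(profile) -> float:
    """Mean divisions per precursor cell: sum i*P_i / sum P_i, P_i = n_i/2^i."""
    counts = _counts(profile)
    i = np.arange(len(counts))
    precursors = counts / 2.0**i
    return float((i * precursors).sum() / precursors.sum())


def normalize_mfi(value, reference):
    """MFI normalized to a reference (healthy-donor or unstimulated) sample."""
    value = np.asarray(value, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference MFI must be positive")
    out = value / reference
    return float(out) if out.ndim == 0 else out


def fold_change_stim(stim: float, unstim: float) -> float:
    """Stimulated / matched-unstimulated intensity ratio for one donor."""
    if unstim <= 0:
        raise ValueError("unstimulated intensity must be positive")
    return stim / unstim


def fold_change_panel(
    table: pd.DataFrame,
    value: str = "mfi",
    donor: str = "donor",
    stimulated: str = "stimulated",
) -> pd.Series:
    """Per-donor stimulated/unstimulated fold-change over a panel.

    Each donor must appear with exactly one stimulated and one unstimulated
    row; anything else raises a pairing error.
    """
    out = {}
    for d, grp in table.groupby(donor):
        s = grp.loc[grp[stimulated].astype(bool), value]
        u = grp.loc[~grp[stimulated].astype(bool), value]
        if len(s) != 1 or len(u) != 1:
            raise ValueError(
                f"donor {d!r} is not a matched stimulated/unstimulated pair"
            )
        out[d] = fold_change_stim(float(s.iloc[0]), float(u.iloc[0]))
    return pd.Series(out, name="fold_change")
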