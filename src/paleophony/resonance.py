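"""Tube-resonance model: harmonic spectra, integrated ranges, beats.

Each airway is idealized as a cylindrical standing-wave resonator.  A tube
open at both ends resonates at ``f_k = k · v / (2L)``; a tube closed at one
end supports only the odd partials, ``f_k = (2k − 1) · v / (4L)``.

A note on counting: "k-th harmonic" here is a *rank* in the resonance
series, not a frequency multiplier.  For a closed-end pipe the 2nd harmonic
in this counting is the first overtone at three times the fundamental —
there is no resonance at twice the fundamental.  This matches the
uniform "1st…5th harmonic" usage in comparative bioacoustics of these
airways and is the convention everywhere in this package.

No open-end correction is applied by default: the idealized model treats
the tube mouth as an exact pressure node.  An optional correction of
``0.6 × radius`` per open end (the classical unflanged-pipe term) can be
switched on for sensitivity checks via ``end_correction_m``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .airway import AirwayPathway
from .errors import AcousticsError

#: Speed of sound in dry air at 20 °C (m/s); the package-wide default.
DEFAULT_SPEED_OF_SOUND = 343.0

#: Default highest harmonic rank analyzed (fundamental through 5th).
DEFAULT_HARMONICS = 5


@dataclass(frozen=True)
class AcousticConfig:
    """Acoustic parameters: speed of sound ``v`` (m/s) and highest harmonic
    rank ``K``."""

    v: float = DEFAULT_SPEED_OF_SOUND
    K: int = DEFAULT_HARMONICS

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise AcousticsError(f"speed of sound must be positive, got {self.v}")
        if not (isinstance(self.K, int) and self.K >= 1):
            raise AcousticsError(f"harmonic count K must be an integer ≥ 1, got {self.K}")


def _multipliers(end_condition: str, K: int) -> np.ndarray:
    if end_condition == "open":
        return np.arange(1, K + 1, dtype=float)
    if end_condition == "closed":
        return np.arange(1, 2 * K, 2, dtype=float)
    raise AcousticsError(f"unknown end condition {end_condition!r}")


def fundamental(length_m: float, end_condition: str,
                v: float = DEFAULT_SPEED_OF_SOUND,
                end_correction_m: float = 0.0) -> float:
    """Fundamental frequency (Hz) of a tube of acoustic length ``length_m``.

    Open-ended: ``v / (2L)``.  Closed-ended: ``v / (4L)``.  A non-zero
    ``end_correction_m`` is added to L once per open end.
    """
    if not (length_m > 0 and v > 0):
        raise AcousticsError(
            f"length and speed of sound must be positive, got L={length_m}, v={v}"
        )
    if end_correction_m < 0:
        raise AcousticsError("end correction must be non-negative")
    if end_condition == "open":
        L_eff = length_m + 2.0 * end_correction_m
        return v / (2.0 * L_eff)
    if end_condition == "closed":
        L_eff = length_m + end_correction_m
        return v / (4.0 * L_eff)
    raise AcousticsError(f"unknown end condition {end_condition!r}")


def invert_length(f1: float, end_condition: str,
                  v: float = DEFAULT_SPEED_OF_SOUND) -> float:
    """Tube length (m) whose fundamental is ``f1``; exact inverse of
    :func:`fundamental` with no end correction."""
    if not (f1 > 0 and v > 0):
        raise AcousticsError(
            f"frequency and speed of sound must be positive, got f1={f1}, v={v}"
        )
    if end_condition == "open":
        return v / (2.0 * f1)
    if end_condition == "closed":
        return v / (4.0 * f1)
    raise AcousticsError(f"unknown end condition {end_condition!r}")


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Resonant frequencies ``f_1..f_K`` (Hz) of one airway pathway."""

    pathway: AirwayPathway
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies) < 1:
            raise AcousticsError("spectrum needs at least one harmonic")
        freqs = tuple(float(f) for f in self.frequencies)
        if any(f <= 0 for f in freqs) or any(
            b <= a for a, b in zip(freqs, freqs[1:])
        ):
            raise AcousticsError(
                "harmonic frequencies must be positive and strictly increasing"
            )
        object.__setattr__(self, "frequencies", freqs)

    @property
    def K(self) -> int:
        return len(self.frequencies)

    def f(self, k: int) -> float:
        """Frequency at harmonic rank ``k`` (1-based)."""
        if not 1 <= k <= self.K:
            raise AcousticsError(f"harmonic rank {k} outside 1..{self.K}")
        return self.frequencies[k - 1]


def harmonic_series(pathway: AirwayPathway,
                    config: AcousticConfig = AcousticConfig(),
                    end_correction_m: float = 0.0) -> HarmonicSpectrum:
    """Spectrum of ``pathway`` under its end-condition model.

    Open tubes use multipliers ``1..K`` on the fundamental; closed tubes the
    odd multipliers ``1, 3, …, 2K−1``.
    """
    f1 = fundamental(pathway.length_m, pathway.end_condition, config.v,
                     end_correction_m)
    mult = _multipliers(pathway.end_condition, config.K)
    return HarmonicSpectrum(pathway, tuple(f1 * mult))


@dataclass(frozen=True)
class FrequencyRange:
    """Closed frequency interval ``[lo, hi]`` at harmonic rank ``k``."""

    k: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise AcousticsError(
                f"range must satisfy 0 < lo ≤ hi, got ({self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


def integrated_range(spectra: Iterable[HarmonicSpectrum],
                     k: int) -> FrequencyRange:
    """Envelope of several airways acting as one integrated resonator:
    ``[min, max]`` of the rank-``k`` frequencies across spectra."""
    values = [s.f(k) for s in spectra]
    if not values:
        raise AcousticsError("integrated_range needs at least one spectrum")
    return FrequencyRange(k=k, lo=min(values), hi=max(values))


@dataclass(frozen=True)
class BeatSeries:
    """Per-rank beat frequencies ``|f_k^A − f_k^B|`` for a pathway pair.

    Two simultaneously excited resonators at nearby frequencies interfere to
    produce amplitude modulation (beats) at the frequency difference.
    """

    pathway_a: AirwayPathway
    pathway_b: AirwayPathway
    beats: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "beats", tuple(float(b) for b in self.beats))
        if any(b < 0 for b in self.beats):
            raise AcousticsError("beat values must be non-negative")


def beat_frequencies(a: HarmonicSpectrum, b: HarmonicSpectrum) -> BeatSeries:
    """Beats between two spectra of equal rank count."""
    if a.K != b.K:
        raise AcousticsError(
            f"spectra have different harmonic counts ({a.K} vs {b.K})"
        )
    beats = tuple(abs(fa - fb) for fa, fb in zip(a.frequencies, b.frequencies))
    return BeatSeries(a.pathway, b.pathway, beats)


# ---------------------------------------------------------------------------
# Tabular output

def spectra_for_pathways(pathways: Sequence[AirwayPathway],
                         config: AcousticConfig = AcousticConfig(),
                         ) -> list[HarmonicSpectrum]:
    if not pathways:
        raise AcousticsError("no airway pathways supplied")
    return [harmonic_series(p, config) for p in pathways]


def spectrum_table(spectra: Sequence[HarmonicSpectrum]) -> pd.DataFrame:
    """Per-pathway spectrum table:
    ``specimen_id,taxon,group,stage,route,end_condition,length_m,f1..fK``."""
    if not spectra:
        raise AcousticsError("no spectra supplied")
    K = spectra[0].K
    if any(s.K != K for s in spectra):
        raise AcousticsError("all spectra must share the same harmonic count")
    rows = []
    for s in spectra:
        p = s.pathway
        rows.append(
            [p.specimen_id, p.taxon, p.group, p.stage, p.route,
             p.end_condition, p.length_m, *s.frequencies]
        )
    cols = ["specimen_id", "taxon", "group", "stage", "route",
            "end_condition", "length_m"] + [f"f{k}" for k in range(1, K + 1)]
    return pd.DataFrame(rows, columns=cols)
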