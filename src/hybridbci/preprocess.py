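"""Filtering, resampling and baselining.

The online path mirrors what a closed-loop system can actually do: causal
(direct-form, second-order-sections) filtering.  Offline analyses may use
zero-phase forward-backward filtering.  Order-5 Butterworth band-pass is
the workhorse for both the oscillatory branch (individual spectral band)
and the slow-potential branch (0.2-4 Hz), designed as SOS for stability at
sub-hertz edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .eeg import BandDefinition, EpochSet, Recording

__all__ = ["FilterSpec", "lowpass_downsample", "bandpass", "baseline_correct"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description, serializable in pipeline configs."""

    kind: str  # "lowpass" | "bandpass"
    band: BandDefinition | float  # band for bandpass, cutoff Hz for lowpass
    order: int = 5
    mode: str = "causal"  # "causal" | "zero-phase"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def design(self, fs: float) -> np.ndarray:
        """Second-order sections for sampling rate *fs*."""
        if self.kind == "lowpass":
            cutoff = float(self.band)  # type: ignore[arg-type]
            if cutoff >= fs / 2:
                raise ValueError(f"cutoff {cutoff} Hz >= Nyquist of fs={fs}")
            sos = sig.butter(self.order, cutoff, btype="low", fs=fs, output="sos")
        else:
            band = self.band
            assert isinstance(band, BandDefinition)
            band.validate_for_fs(fs)
            sos = sig.butter(
                self.order, [band.lo, band.hi], btype="band", fs=fs, output="sos"
            )
        if not _sos_stable(sos):
            raise ArithmeticError(
                "unstable filter design (poles outside unit circle); "
                "reduce the order or widen the band"
            )
        return sos

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "order": self.order, "mode": self.mode}
        if isinstance(self.band, BandDefinition):
            d.update(lo=self.band.lo, hi=self.band.hi, name=self.band.name)
        else:
            d["cutoff"] = float(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        if "cutoff" in d:
            band: BandDefinition | float = float(d["cutoff"])
        else:
            band = BandDefinition(d["lo"], d["hi"], d.get("name", ""))
        return cls(kind=d["kind"], band=band, order=d.get("order", 5),
                   mode=d.get("mode", "causal"))


def _sos_stable(sos: np.ndarray) -> bool:
    _, poles, _ = sig.sos2zpk(sos)
    return bool(np.all(np.abs(poles) < 1.0))


def _apply_sos(x: np.ndarray, sos: np.ndarray, mode: str) -> np.ndarray:
    if mode == "zero-phase":
        return sig.sosfiltfilt(sos, x, axis=-1)
    return sig.sosfilt(sos, x, axis=-1)


def lowpass_downsample(
    rec: Recording, cutoff_hz: float = 45.0, fs_out: float = 100.0
) -> Recording:
    """Anti-alias low-pass then decimate a continuous recording.

    Marker sample indices are rescaled by ``fs_out/fs`` and rounded down.
    The anti-alias filter is a zero-phase order-5 Butterworth low-pass at
    *cutoff_hz* (applied before any decimation).
    """
    if fs_out > rec.fs:
        raise ValueError(f"fs_out={fs_out} exceeds recording fs={rec.fs}")
    if cutoff_hz >= fs_out / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist of the target rate {fs_out} Hz"
        )
    spec = FilterSpec(kind="lowpass", band=cutoff_hz, order=5, mode="zero-phase")
    filtered = _apply_sos(rec.signal, spec.design(rec.fs), "zero-phase")

    ratio = rec.fs / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
        out = sig.resample_poly(filtered, frac.numerator, frac.denominator, axis=-1)
    n_out = out.shape[1]
    markers = [
        type(m)(sample=int(m.sample * fs_out / rec.fs), label=m.label)
        for m in rec.markers
        if int(m.sample * fs_out / rec.fs) < n_out
    ]
    return Recording(
        signal=out, fs=fs_out, channel_labels=list(rec.channel_labels),
        markers=markers,
    )


def bandpass(x: Recording | EpochSet, spec: FilterSpec):
    """Filter a Recording or EpochSet along time; returns the same type."""
    if isinstance(x, Recording):
        sos = spec.design(x.fs)
        return Recording(
            signal=_apply_sos(x.signal, sos, spec.mode),
            fs=x.fs,
            channel_labels=list(x.channel_labels),
            markers=list(x.markers),
        )
    sos = spec.design(x.fs)
    return x.copy_with(_apply_sos(x.data, sos, spec.mode))


def baseline_correct(
    ep: EpochSet, interval: tuple[float, float] = (-300.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over *interval* (ms).

    The default interval is the 300 ms before trial onset.  Idempotent.
    """
    mask = ep.time_mask(interval)
    baseline = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return ep.copy_with(ep.data - baseline)
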