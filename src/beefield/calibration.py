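"""Electric-field quantification and electrometer calibration.

The stimulus electrode is a small conductive sphere driven by a sinewave;
treated as a point source, the RMS field it radiates falls off inversely
with distance,

    E_RMS = V_RMS / r,

with ``V_RMS = Vpp / (2 sqrt(2))`` for a sinewave of peak-to-peak amplitude
Vpp and ``r`` the distance from the electrode centre in metres.

Survey-meter measurements of the real setup deviate from the point-source
model in a distance-dependent way (the plant and enclosure perturb the
field), but measured and modelled values are strongly linearly related
within a near band (60-300 mm) and a far band (360-600 mm) separately. The
calibration chain is therefore:

1. baseline-subtract the unpowered (grounded-electrode) control measurements
   from the stimulus measurements to remove ambient mains pickup;
2. fit one ordinary-least-squares line per band, measured ~ modelled;
3. push the point-source field at each electrometer's anchor distance (70 mm
   near, 400 mm far) through its band's line to get the anchor field;
4. divide the anchor field by the mean electric potential the electrometer
   recorded with no plant present — that scalar (V/m per recorded volt) is
   the electrometer's calibration factor.

Recorded waveforms are low-pass filtered (zero-phase, 4th-order Butterworth,
30 Hz default) to isolate the 20 Hz stimulus from 50 Hz mains noise before
taking the RMS and applying the factor. All lengths are metres at the API
boundary; millimetre figures from lab notes must be converted on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "NEAR_RANGE_M",
    "FAR_RANGE_M",
    "StimulusSpec",
    "WaveformRecording",
    "CalibrationModel",
    "vpp_to_vrms",
    "point_source_field",
    "baseline_subtract",
    "fit_piecewise_calibration",
    "calibration_factor",
    "waveform_to_field",
    "condition_summary",
]

NEAR_RANGE_M = (0.060, 0.300)
FAR_RANGE_M = (0.360, 0.600)

#: lab measurement conditions (plant manipulations and their unpowered controls)
CONDITIONS = (
    "grounded_plant",
    "floating_plant",
    "no_plant",
    "grounded_electrode_control",
    "floating_electrode_control",
    "no_electrode_control",
)


@dataclass(frozen=True)
class StimulusSpec:
    """Applied electrical stimulus (e.g. 5 Vpp 20 Hz sine for calibration)."""

    vpp: float
    frequency_hz: float
    polarity: str = "AC"

    def __post_init__(self) -> None:
        if self.polarity == "AC":
            if self.vpp <= 0:
                raise ValueError("vpp must be positive for an AC stimulus")
            if self.frequency_hz <= 0:
                raise ValueError("frequency must be positive for an AC stimulus")

    @property
    def vrms(self) -> float:
        return vpp_to_vrms(self.vpp)


@dataclass
class WaveformRecording:
    """Electrometer output trace: sample rate, samples (V), anchor distance."""

    sample_rate_hz: float
    samples: np.ndarray
    distance_m: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("waveform recording is empty")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")


def vpp_to_vrms(vpp: float) -> float:
    """RMS of a sinewave from its peak-to-peak amplitude: Vpp / (2 sqrt 2)."""
    if vpp < 0:
        raise ValueError("peak-to-peak voltage cannot be negative")
    return vpp / (2.0 * np.sqrt(2.0))


def point_source_field(vrms: float, r_m) -> float | np.ndarray:
    """Point-source RMS field E = V_RMS / r, in V/m (r in metres)."""
    r = np.asarray(r_m, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive: the point-source field is singular at r=0")
    out = vrms / r
    return out if out.ndim else float(out)


def _series(values, name: str) -> pd.Series:
    s = pd.Series(values) if not isinstance(values, pd.Series) else values.copy()
    s.index = s.index.astype(float)
    s.index.name = "distance_m"
    s.name = name
    return s.sort_index()


def baseline_subtract(stimulus, control) -> pd.Series:
    """Subtract unpowered-control field magnitudes from stimulus magnitudes.

    Both inputs are Series indexed by distance (m); the grids must match.
    Differences are floored at 0 with a warning, since a field magnitude
    cannot be negative and both operands are noisy magnitudes.
    """
    stim = _series(stimulus, "stimulus")
    ctrl = _series(control, "control")
    missing = sorted(set(stim.index).symmetric_difference(ctrl.index))
    if missing:
        raise ValueError(
            f"stimulus and control distance grids differ at distances {missing} (m)"
        )
    diff = stim - ctrl
    neg = diff < 0
    if neg.any():
        warnings.warn(
            f"baseline exceeded stimulus at {int(neg.sum())} distance(s); "
            "flooring corrected field at 0",
            stacklevel=2,
        )
        diff[neg] = 0.0
    diff.name = "corrected"
    return diff


@dataclass
class CalibrationModel:
    """Near/far calibration lines plus per-electrometer factors.

    Slopes/intercepts map the point-source (modelled) field to the field a
    survey meter would measure in that band; ``anchor_fields_vpm`` caches the
    predicted fields at the electrometer positions; ``factors`` holds the
    V/m-per-volt scalars keyed by anchor distance.
    """

    near_slope: float
    near_intercept: float
    near_r2: float
    far_slope: float
    far_intercept: float
    far_r2: float
    near_range_m: tuple[float, float] = NEAR_RANGE_M
    far_range_m: tuple[float, float] = FAR_RANGE_M
    anchor_fields_vpm: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)

    def band(self, distance_m: float) -> str:
        if self.near_range_m[0] <= distance_m <= self.near_range_m[1]:
            return "near"
        if self.far_range_m[0] <= distance_m <= self.far_range_m[1]:
            return "far"
        raise ValueError(
            f"distance {distance_m} m falls outside both calibration bands "
            f"(near {self.near_range_m}, far {self.far_range_m}); no line is "
            "fitted in the gap"
        )

    def predict_measured(self, modeled_vpm, distance_m: float) -> float | np.ndarray:
        """Expected survey-meter field for a point-source field at a distance."""
        if self.band(distance_m) == "near":
            return self.near_slope * np.asarray(modeled_vpm, float) + self.near_intercept
        return self.far_slope * np.asarray(modeled_vpm, float) + self.far_intercept


def fit_piecewise_calibration(
    measured,
    modeled,
    near_range_m: tuple[float, float] = NEAR_RANGE_M,
    far_range_m: tuple[float, float] = FAR_RANGE_M,
) -> CalibrationModel:
    """OLS lines (measured ~ modelled) per distance band.

    Both inputs are Series indexed by distance in metres; each band needs at
    least 2 points. The bands must not overlap.
    """
    if near_range_m[1] >= far_range_m[0]:
        raise ValueError("near and far ranges must not overlap")
    meas = _series(measured, "measured")
    mod = _series(modeled, "modeled")
    if list(meas.index) != list(mod.index):
        raise ValueError("measured and modeled series must share a distance grid")
    fits = {}
    for name, (lo, hi) in (("near", near_range_m), ("far", far_range_m)):
        in_band = (meas.index >= lo - 1e-12) & (meas.index <= hi + 1e-12)
        if in_band.sum() < 2:
            raise ValueError(
                f"{name} range {lo}-{hi} m has {int(in_band.sum())} point(s); "
                "need at least 2 to fit a line"
            )
        res = stats.linregress(mod[in_band].to_numpy(), meas[in_band].to_numpy())
        fits[name] = (float(res.slope), float(res.intercept), float(res.rvalue) ** 2)
    return CalibrationModel(
        *fits["near"], *fits["far"], near_range_m=near_range_m, far_range_m=far_range_m
    )


def calibration_factor(
    model: CalibrationModel,
    anchor_distance_m: float,
    mean_potential_v: float,
    vrms: float = vpp_to_vrms(5.0),
) -> float:
    """Per-electrometer scalar mapping recorded volts to field strength.

    The anchor field is the point-source field at the anchor distance pushed
    through the band's calibration line; the factor divides it by the mean
    potential recorded there with no plant present. The factor and anchor
    field are stored on the model, keyed by distance.
    """
    if mean_potential_v <= 0:
        raise ValueError("mean recorded potential must be positive")
    anchor_field = float(
        model.predict_measured(point_source_field(vrms, anchor_distance_m), anchor_distance_m)
    )
    factor = anchor_field / mean_potential_v
    model.anchor_fields_vpm[anchor_distance_m] = anchor_field
    model.factors[anchor_distance_m] = factor
    return factor


def waveform_to_field(
    rec: WaveformRecording,
    factor: float,
    cutoff_hz: float = 30.0,
    order: int = 4,
) -> float:
    """Calibrated RMS field from a recorded trace.

    Zero-phase (forward-backward) Butterworth low-pass at ``cutoff_hz``
    isolates the stimulus from higher-frequency mains noise, then the RMS of
    the filtered trace is scaled by the calibration factor.
    """
    nyquist = rec.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    rms = float(np.sqrt(np.mean(filtered**2)))
    return rms * factor


def condition_summary(fields: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of calibrated fields per condition/distance cell.

    ``fields`` has columns ``condition, distance_m, efield_vpm``. Cells with
    a single value report SD as NaN (not applicable); min/max per cell are
    included. Conditions absent from the data are simply absent (missing,
    not zero).
    """
    required = {"condition", "distance_m", "efield_vpm"}
    missing = required - set(fields.columns)
    if missing:
        raise ValueError(f"field table is missing columns: {sorted(missing)}")
    if len(fields) == 0:
        raise ValueError("field table is empty")
    out = (
        fields.groupby(["condition", "distance_m"])["efield_vpm"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count", min="min", max="max")
        .reset_index()
    )
    return out
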