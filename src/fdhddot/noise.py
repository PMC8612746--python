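"""Empirical measurement-noise model for FD high-density optical tomography.

The standard deviation of measurement noise is a two-term exponential in the
source-detector distance r (mm), scaled by a power-of-ten factor in the
modulation frequency f (MHz), normalized so the frequency factor is 1 at
140 MHz (the frequency at which the distance model was measured):

    N(r, f) = (a * exp(b*r) + c * exp(d*r)) * 10^(g * (f - 140)).

Intensity noise is expressed in percent of the amplitude, phase noise in
degrees; both are converted exactly once at injection time (percent ->
additive log-amplitude noise via the small-noise equivalence, degrees ->
radians).  For one channel the intensity and phase draws are coupled via a
matched standard-normal variate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import MeasurementSet

#: Empirical coefficients per (wavelength nm, datum type):
#: (a [% or deg], b [mm^-1], c [% or deg], d [mm^-1], g [MHz^-1]).
DEFAULT_NOISE_COEFFS: dict[tuple[int, str], tuple[float, float, float, float, float]] = {
    (690, "intensity"): (0.2502, 0.02913, 4.625e-06, 0.2128, 6.769e-04),
    (850, "intensity"): (0.6019, 0.01052, 9.685e-05, 0.1382, 6.785e-04),
    (690, "phase"): (3.933e-11, 0.4161, 0.0105, 0.05585, 0.0013),
    (850, "phase"): (1.917e-10, 0.3708, 0.03573, 0.02002, 0.0013),
}

REFERENCE_FREQUENCY_MHZ = 140.0


class NoiseConfigurationError(KeyError):
    """Raised for an unknown wavelength / datum-type combination."""


@dataclass
class NoiseModelParams:
    """Coefficient table of the empirical noise model."""

    coeffs: dict[tuple[int, str], tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_COEFFS)
    )

    def get(self, wavelength: int, datum_type: str):
        try:
            return self.coeffs[(int(wavelength), datum_type)]
        except KeyError as exc:
            raise NoiseConfigurationError(
                f"no noise coefficients for ({wavelength} nm, {datum_type})"
            ) from exc


@dataclass
class NoiseRealization:
    """One coupled draw of measurement noise for a channel set.

    ``intensity`` is in additive log-amplitude units (dimensionless),
    ``phase`` in radians (``None`` for the continuous-wave case).
    """

    intensity: np.ndarray
    phase: np.ndarray | None
    seed: object
    frequency: float


def noise_std(
    r,
    f: float,
    wavelength: int,
    datum_type: str,
    params: NoiseModelParams | None = None,
):
    """Noise standard deviation: percent for intensity, degrees for phase."""
    if params is None:
        params = NoiseModelParams()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or f < 0:
        raise ValueError("separation and frequency must be non-negative")
    a, b, c, d, g = params.get(wavelength, datum_type)
    out = (a * np.exp(b * r) + c * np.exp(d * r)) * 10.0 ** (
        g * (f - REFERENCE_FREQUENCY_MHZ)
    )
    return out if out.shape else float(out)


def sample_noise(
    channels: MeasurementSet,
    f: float,
    wavelength: int,
    seed,
    params: NoiseModelParams | None = None,
    coupled: bool = True,
    scale: float = 1.0,
) -> NoiseRealization:
    """Draw one zero-mean Gaussian noise realization for every channel.

    Each channel gets one standard-normal draw z; the intensity component is
    z * sigma_I(r, f) / 100 (percent -> relative -> log-amplitude) and the
    phase component z * sigma_theta(r, f) * pi / 180 (degrees -> radians).
    With ``coupled=False`` the phase draw is independent (sensitivity
    analysis).  Continuous-wave (f = 0) realizations contain intensity only.

    ``scale`` multiplies both standard deviations at injection time; it
    represents the effective averaging of the differential datum (the noise
    model describes a single measurement sample, whereas a differential
    activation datum is an average over a recording block), and leaves the
    noise model itself untouched.
    """
    rng = np.random.default_rng(seed)
    r = channels.separations
    z = rng.standard_normal(channels.n_channels)
    sigma_i = noise_std(r, f, wavelength, "intensity", params)
    intensity = z * sigma_i / 100.0 * scale
    if f == 0.0:
        return NoiseRealization(intensity, None, seed, f)
    zp = z if coupled else rng.standard_normal(channels.n_channels)
    sigma_p = noise_std(r, f, wavelength, "phase", params)
    phase = zp * sigma_p * np.pi / 180.0 * scale
    return NoiseRealization(intensity, phase, seed, f)


def derive_noise_seed(
    master_seed: int, voxel_id: int, frequency: float, wavelength: int,
    realization: int = 0,
) -> np.random.SeedSequence:
    """Documented seed-derivation rule for per-(voxel, frequency,
    wavelength, realization) noise draws."""
    return np.random.SeedSequence(
        entropy=(
            int(master_seed),
            int(voxel_id),
            int(round(frequency)),
            int(wavelength),
            int(realization),
        )
    )
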