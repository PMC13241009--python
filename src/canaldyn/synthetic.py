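"""Synthetic cohorts of tuned-neuron ΔF/F traces.

The generator emulates the statistical structure the analysis pipeline
assumes in real tectal recordings: a population of direction-selective,
orientation-selective and visually unresponsive neurons whose stimulus
drive is shaped by a von Mises tuning curve, low-pass filtered by slow
calcium-indicator kinetics, and corrupted by trial-to-trial noise.

A *cohort* of individuals shares a single tuning blueprint.  In the
canalized regime (``decanalization_sd = 0``) every individual is the same
population up to imaging noise, mimicking strongly buffered development.
Decanalization is modelled as independent per-individual perturbations of
the blueprint: Gaussian jitter of each neuron's preferred angle (SD
``decanalization_sd`` degrees) and log-normal scaling of its response
amplitude (log-SD ``decanalization_sd / 100``), a single knob that widens
the between-individual spread of the evoked dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .protocol import StimulusProtocol, default_protocol, trial_windows, stimulus_window

CLASS_DIRECTION = "direction"
CLASS_ORIENTATION = "orientation"
CLASS_UNTUNED = "untuned"
CLASSES = (CLASS_DIRECTION, CLASS_ORIENTATION, CLASS_UNTUNED)


@dataclass
class TuningPopulation:
    """Per-neuron tuning parameters of one (blueprint or perturbed) population."""

    preferred_angle_deg: np.ndarray  # degrees in [0, 360)
    kappa: np.ndarray                # von Mises concentration, >= 0
    selectivity_class: np.ndarray    # strings from CLASSES
    amplitude: np.ndarray            # peak evoked dF/F, >= 0
    baseline: np.ndarray             # resting dF/F

    def __post_init__(self) -> None:
        n = len(self.preferred_angle_deg)
        for name in ("kappa", "selectivity_class", "amplitude", "baseline"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-neuron arrays must have equal length")
        if np.any(self.kappa < 0) or np.any(self.amplitude < 0):
            raise ValueError("kappa and amplitude must be non-negative")
        bad = set(np.unique(self.selectivity_class)) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown selectivity classes: {bad}")

    @property
    def n_neurons(self) -> int:
        return len(self.preferred_angle_deg)


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    ``decanalization_sd`` (σ_d, degrees) is the single decanalization knob:
    it sets the SD of per-individual preferred-angle jitter and, divided by
    100, the log-SD of the per-individual amplitude multiplier.  σ_d = 0
    gives a canalized cohort in which all individuals share the identical
    blueprint up to imaging noise.  ``trial_noise_sd`` is the SD of iid
    Gaussian noise added to every sample, expressed as a fraction of that
    neuron's noiseless signal SD.
    """

    n_fish: int = 9
    n_neurons: int = 250
    class_fractions: tuple[float, float, float] = (0.3, 0.3, 0.4)
    kappa_range: tuple[float, float] = (2.0, 8.0)
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    baseline_range: tuple[float, float] = (0.05, 0.15)
    decanalization_sd: float = 0.0
    trial_noise_sd: float = 0.1
    calcium_tau_s: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1 or self.n_neurons < 1:
            raise ValueError("n_fish and n_neurons must be >= 1")
        f = self.class_fractions
        if len(f) != 3 or any(x < 0 or x > 1 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("class_fractions must be three values in [0,1] summing to 1")
        if self.decanalization_sd < 0 or self.trial_noise_sd < 0:
            raise ValueError("decanalization_sd and trial_noise_sd must be >= 0")
        if self.calcium_tau_s < 0:
            raise ValueError("calcium_tau_s must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("class_fractions", "kappa_range", "amplitude_range", "baseline_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TraceSet:
    """One individual's ΔF/F matrix (neurons × timepoints) with metadata."""

    fish_id: str
    genotype: str
    dff: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be a 2-D (neurons × timepoints) matrix")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        if self.dff.shape[1] != self.protocol.total_samples:
            raise ValueError(
                f"dff has {self.dff.shape[1]} timepoints but the protocol timeline "
                f"is {self.protocol.total_samples} samples"
            )

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.dff.shape[1]


def largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``fractions``.

    Largest-remainder method: floor each share, then hand remaining units to
    the largest fractional parts (ties to the lowest index).  Deterministic
    and exact: counts always sum to ``total``.
    """
    shares = [f * total for f in fractions]
    counts = [int(np.floor(s)) for s in shares]
    remainder = total - sum(counts)
    order = sorted(range(len(shares)), key=lambda i: (-(shares[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_blueprint(spec: CohortSpec, seed: int | None = None) -> TuningPopulation:
    """Draw the cohort's shared tuning blueprint.

    Class counts follow largest-remainder apportionment of
    ``spec.class_fractions``; preferred angles are uniform on [0, 360),
    concentrations and amplitudes uniform on their ranges.  Deterministic
    given the seed (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_neurons
    counts = largest_remainder(spec.class_fractions, n)
    classes = np.repeat(np.array(CLASSES, dtype=object), counts)
    return TuningPopulation(
        preferred_angle_deg=rng.uniform(0.0, 360.0, n),
        kappa=rng.uniform(*spec.kappa_range, n),
        selectivity_class=classes,
        amplitude=rng.uniform(*spec.amplitude_range, n),
        baseline=rng.uniform(*spec.baseline_range, n),
    )


def tuning_response(pop: TuningPopulation, neuron: int, direction_deg: float) -> float:
    """Evoked drive of one neuron to a grating moving at ``direction_deg``.

    Direction-selective cells follow a von Mises curve with period 360°,
    orientation-selective cells one with period 180°; both peak at the
    neuron's amplitude when probed at its preferred angle.  Untuned cells
    contribute no evoked drive (their trace is their baseline).

    Angle differences are reduced modulo the period in degrees before the
    cosine, so probes exactly one period apart give bit-identical drives.
    """
    cls = pop.selectivity_class[neuron]
    if cls == CLASS_UNTUNED:
        return 0.0
    a = float(pop.amplitude[neuron])
    k = float(pop.kappa[neuron])
    pref = float(pop.preferred_angle_deg[neuron])
    # reduce each angle modulo the period *before* subtracting so that probes
    # exactly one period apart give bit-identical drives
    if cls == CLASS_DIRECTION:
        delta = (direction_deg % 360.0 - pref % 360.0) % 360.0
        return a * float(np.exp(k * (np.cos(np.deg2rad(delta)) - 1.0)))
    delta = (direction_deg % 180.0 - pref % 180.0) % 180.0
    return a * float(np.exp(k * (np.cos(np.deg2rad(2.0 * delta)) - 1.0)))


def evoked_matrix(pop: TuningPopulation, directions_deg: Sequence[float]) -> np.ndarray:
    """Evoked drives for all neurons × all stimulus directions."""
    out = np.zeros((pop.n_neurons, len(directions_deg)))
    for i in range(pop.n_neurons):
        for j, d in enumerate(directions_deg):
            out[i, j] = tuning_response(pop, i, d)
    return out


def _calcium_filter(
    drive: np.ndarray, tau_s: float, rate_hz: float, support_samples: int | None = None
) -> np.ndarray:
    """Convolve each row with a causal exponential kernel of unit peak.

    The kernel exp(-t/τ) is truncated at ``support_samples`` (when given) so
    that a response decays fully within its own gray gap and never leaks
    into the next direction's window; with the default τ = 1.5 s against a
    10 s gap the discarded tail is < 0.2% of the peak.  The truncation keeps
    per-direction amplitudes exactly slot-local, so tuning curves with exact
    angular symmetries stay exactly symmetric after filtering.  τ ≤ 0
    reduces to the identity (delta kernel).
    """
    if tau_s <= 0:
        return drive.copy()
    if support_samples is None:
        support_samples = int(np.ceil(10.0 * tau_s * rate_hz)) + 1
    support_samples = max(int(support_samples), 1)
    j = np.arange(support_samples)
    kernel = np.exp(-j / (tau_s * rate_hz))
    return lfilter(kernel, [1.0], drive, axis=-1)


def simulate_individual(
    blueprint: TuningPopulation,
    p: StimulusProtocol,
    spec: CohortSpec,
    individual_seed: int | np.random.Generator = 0,
    fish_id: str = "fish00",
    genotype: str = "wt",
) -> TraceSet:
    """Simulate one individual's ΔF/F traces under the protocol.

    The evoked drive is a step time series (each neuron's tuning drive held
    during each stimulus-on window, zero otherwise) filtered by the calcium
    kernel; the trace is baseline + filtered drive + iid Gaussian noise of
    SD = ``spec.trial_noise_sd`` × that neuron's noiseless signal SD.
    """
    rng = (
        individual_seed
        if isinstance(individual_seed, np.random.Generator)
        else np.random.default_rng(individual_seed)
    )
    n, total = blueprint.n_neurons, p.total_samples
    ev = evoked_matrix(blueprint, p.directions_deg)
    drive = np.zeros((n, total))
    for _, t0, _ in trial_windows(p):
        for d in range(p.n_directions):
            s0, s1 = stimulus_window(p, d)
            drive[:, t0 + s0 : t0 + s1] = ev[:, d][:, None]
    signal = _calcium_filter(
        drive, spec.calcium_tau_s, p.sample_rate_hz, support_samples=p.gap_samples + 1
    )
    noise_sd = spec.trial_noise_sd * signal.std(axis=1, ddof=0)
    dff = blueprint.baseline[:, None] + signal
    if spec.trial_noise_sd > 0:
        dff = dff + rng.standard_normal((n, total)) * noise_sd[:, None]
    return TraceSet(fish_id=fish_id, genotype=genotype, dff=dff, protocol=p)


def perturb_blueprint(
    blueprint: TuningPopulation, sd_deg: float, rng: np.random.Generator
) -> TuningPopulation:
    """One individual's developmental deviation from the shared blueprint:
    angle jitter ~ Normal(0, sd_deg) and amplitude × LogNormal(0, sd_deg/100)."""
    n = blueprint.n_neurons
    angles = (blueprint.preferred_angle_deg + rng.normal(0.0, sd_deg, n)) % 360.0
    amps = blueprint.amplitude * rng.lognormal(0.0, sd_deg / 100.0, n)
    return TuningPopulation(
        preferred_angle_deg=angles,
        kappa=blueprint.kappa.copy(),
        selectivity_class=blueprint.selectivity_class.copy(),
        amplitude=amps,
        baseline=blueprint.baseline.copy(),
    )


def simulate_cohort(
    spec: CohortSpec,
    genotype_label: str = "wt",
    protocol: StimulusProtocol | None = None,
) -> list[TraceSet]:
    """Simulate a cohort of individuals sharing one tuning blueprint.

    Individual i draws its perturbation and noise from a generator seeded
    ``spec.seed + 1 + i`` (offset so no individual shares the blueprint's
    stream), so cohorts are bit-reproducible and extendable fish by fish.
    """
    p = protocol if protocol is not None else default_protocol()
    blueprint = make_blueprint(spec)
    cohort = []
    for i in range(spec.n_fish):
        rng = np.random.default_rng(spec.seed + 1 + i)
        pop = (
            perturb_blueprint(blueprint, spec.decanalization_sd, rng)
            if spec.decanalization_sd > 0
            else blueprint
        )
        ts = simulate_individual(
            pop, p, spec, rng, fish_id=f"{genotype_label}{i:02d}", genotype=genotype_label
        )
        cohort.append(ts)
    return cohort


def simulate_lowrank_trial_average(
    protocol: StimulusProtocol | None = None,
    n_neurons: int = 250,
    k: int = 5,
    noise_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """A trial-averaged population matrix that is exactly rank ``k`` plus noise.

    ``k`` stimulus-locked mode time courses (calcium-filtered evoked drives
    of archetype tuned cells, mean-centered) are mixed by Gaussian neuron
    loadings; iid Gaussian noise is added with total variance
    noise_fraction/(1-noise_fraction) × the signal's total centered variance
    (0.1 → noise variance equal to one-ninth of signal variance, i.e. 10%
    of the total).  Returns a (neurons × T_trial) matrix.
    """
    if not (0 <= noise_fraction < 1):
        raise ValueError("noise_fraction must be in [0, 1)")
    p = protocol if protocol is not None else default_protocol()
    rng = np.random.default_rng(seed)
    T = p.trial_samples
    # archetype time courses: direction/orientation cells at spread angles
    angles = np.linspace(0.0, 360.0, k, endpoint=False)
    classes = np.array(
        [CLASS_DIRECTION if i % 2 == 0 else CLASS_ORIENTATION for i in range(k)], dtype=object
    )
    arche = TuningPopulation(
        preferred_angle_deg=angles,
        kappa=np.linspace(2.0, 6.0, k),
        selectivity_class=classes,
        amplitude=np.ones(k),
        baseline=np.zeros(k),
    )
    ev = evoked_matrix(arche, p.directions_deg)
    drive = np.zeros((k, T))
    for d in range(p.n_directions):
        s0, s1 = stimulus_window(p, d)
        drive[:, s0:s1] = ev[:, d][:, None]
    patterns = _calcium_filter(drive, 1.5, p.sample_rate_hz, support_samples=p.gap_samples + 1)
    patterns = patterns - patterns.mean(axis=1, keepdims=True)
    loadings = rng.standard_normal((n_neurons, k))
    signal = loadings @ patterns
    centered = signal - signal.mean(axis=1, keepdims=True)
    signal_var = float(np.sum(centered**2) / centered.size)
    noise_var = signal_var * noise_fraction / (1.0 - noise_fraction)
    noise = rng.standard_normal((n_neurons, T)) * np.sqrt(noise_var)
    return signal + noise
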