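"""Synthetic phospho-array time courses with known signal kinetics.

Each active molecule carries a transient phosphorylation pulse: intensity
rises linearly from baseline to a peak at ``t_peak`` and returns linearly to
baseline at ``tau_true`` (triangular pulse). The triangular shape is a
deliberate stand-in — real phosphorylation kinetics are smooth, and published
time courses only constrain the qualitative rise (within ~15 min) and decay
(back to baseline within ~3 h). Piecewise linearity makes both the
linear zero-crossing duration estimator and trapezoidal integration exact,
so every downstream stage has closed-form ground truth:

    beta_true = ln(1 + A / (2 * baseline)) / tau_true   [1/min]

because the triangle's area over [0, tau_true] is A*tau_true/2.

Noise model
-----------
Two multiplicative lognormal components, both mean-1:

* spot noise, CV ``noise_cv`` (default 0.08), independent per record —
  fluorescence measurement error; the assay's replicate CV is < 0.1;
* a per-replicate response-strength effect gamma_i (mean-1 log-uniform,
  CV ``replicate_effect_cv``, default 0.45), shared by *every* molecule in
  that replicate. A replicate is a whole independent stimulation
  experiment, so biological signaling efficiency varies together across
  molecules on one array. The effect acts at the rate level: replicate i of
  an active molecule realizes the information gain
  gamma_i * beta_true * tau_true, i.e. its pulse amplitude is
  2*baseline*((1 + A/(2*baseline))**gamma_i - 1). Consequently the
  per-replicate STR is exactly gamma_i * beta_true (before spot noise): the
  replicate mean is an unbiased estimate of beta_true, the replicate STR
  spread is multiplicative — as published array box plots show — and
  equal-rate molecules move together across replicates, with only spot
  noise left in their difference. The effect is log-uniform (bounded)
  rather than lognormal: biological response variation is bounded, and a
  heavy-tailed effect would generate spurious boxplot "outliers" that the
  trimming step — meant for technical failures — would then remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import NEGCTRL_ID, PhosphoArrayDataset


class ConfigurationError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class MoleculeSpec:
    """Ground-truth kinetics of one signaling molecule.

    ``pulse_amplitude`` is the peak intensity increment above baseline
    (arbitrary units); a molecule with zero amplitude is inactive.
    ``total_intensity`` is the constant unphosphorylated-protein channel
    level (defaults to 5x baseline).
    """

    molecule_id: str
    baseline_intensity: float = 100.0
    pulse_amplitude: float = 0.0
    t_peak: float = 15.0
    tau_true: float = 45.0
    total_intensity: float | None = None

    def __post_init__(self):
        if self.baseline_intensity <= 0:
            raise ConfigurationError(f"{self.molecule_id}: baseline must be > 0")
        if self.pulse_amplitude < 0:
            raise ConfigurationError(f"{self.molecule_id}: amplitude must be >= 0")
        if not (self.tau_true > self.t_peak > 0):
            raise ConfigurationError(
                f"{self.molecule_id}: need tau_true > t_peak > 0, "
                f"got t_peak={self.t_peak}, tau_true={self.tau_true}"
            )
        if self.total_intensity is None:
            object.__setattr__(self, "total_intensity", 5.0 * self.baseline_intensity)

    @property
    def active(self) -> bool:
        return self.pulse_amplitude > 0


DEFAULT_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 120.0, 180.0)


@dataclass(frozen=True)
class DatasetSpec:
    """Full specification of one simulated array experiment."""

    molecules: tuple[MoleculeSpec, ...]
    time_grid: tuple[float, ...] = DEFAULT_GRID
    n_replicates: int = 6
    noise_cv: float = 0.08
    replicate_effect_cv: float = 0.45
    negctrl_level: float = 100.0
    condition: str = ""
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "molecules", tuple(self.molecules))
        object.__setattr__(self, "time_grid", tuple(float(t) for t in self.time_grid))
        grid = np.asarray(self.time_grid)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("time_grid must start at 0 and strictly increase")
        if self.n_replicates < 5:
            raise ConfigurationError("need n_replicates >= 5 (outlier trimming floor)")
        if not (0 <= self.noise_cv < 1):
            raise ConfigurationError("noise_cv must be in [0, 1)")
        if self.replicate_effect_cv < 0:
            raise ConfigurationError("replicate_effect_cv must be >= 0")


def pulse_value(spec: MoleculeSpec, t: float) -> float:
    """Noise-free pulse increment above baseline at time ``t`` (min).

    Rises linearly 0 -> A on [0, t_peak], falls linearly A -> 0 on
    [t_peak, tau_true], zero afterwards. Continuous and nonnegative.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    a, tp, tau = spec.pulse_amplitude, spec.t_peak, spec.tau_true
    if t <= tp:
        return a * t / tp
    if t <= tau:
        return a * (tau - t) / (tau - tp)
    return 0.0


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given coefficient of
    variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _loguniform_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-uniform factors: exp(U(-a, a)) rescaled to
    unit mean, with a = sqrt(3)*cv so the coefficient of variation is
    approximately ``cv``. Bounded support — never produces boxplot
    outliers."""
    if cv == 0:
        return np.ones(size)
    a = np.sqrt(3.0) * cv
    raw = np.exp(rng.uniform(-a, a, size=size))
    return raw / (np.sinh(a) / a)


def generate_dataset(spec: DatasetSpec) -> PhosphoArrayDataset:
    """Simulate one array experiment.

    phospho(t)  = (baseline + A_i * shape(t)) * eps
    total(t)    = total_intensity * eps'
    negctrl(t)  = negctrl_level * eps''

    where eps are independent mean-1 lognormal spot-noise factors
    (CV ``noise_cv``), shape(t) is the unit triangular pulse, and A_i is the
    replicate-specific amplitude realizing the rate-level response effect:
    A_i = 2*baseline*((1 + A/(2*baseline))**gamma_i - 1) with gamma_i the
    shared per-replicate response strength (mean-1 log-uniform, CV
    ``replicate_effect_cv``), so replicate i of every active molecule
    carries the information gain gamma_i * beta_true * tau_true.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.time_grid)
    nt, nr = len(times), spec.n_replicates
    gamma = _loguniform_factors(rng, spec.replicate_effect_cv, nr)

    rows: list[pd.DataFrame] = []
    for mol in spec.molecules:
        shape = np.array(
            [pulse_value(mol, t) / mol.pulse_amplitude if mol.active else 0.0
             for t in times]
        )
        fold = 1.0 + mol.pulse_amplitude / (2.0 * mol.baseline_intensity)
        amp = 2.0 * mol.baseline_intensity * (fold ** gamma - 1.0)
        # shape (time, replicate)
        clean = mol.baseline_intensity + shape[:, None] * amp[None, :]
        phospho = clean * _lognormal_factors(rng, spec.noise_cv, (nt, nr))
        total = mol.total_intensity * _lognormal_factors(rng, spec.noise_cv, (nt, nr))
        for name, arr in (("phospho", phospho), ("total", total)):
            rows.append(
                pd.DataFrame(
                    {
                        "molecule_id": mol.molecule_id,
                        "channel": name,
                        "time_min": np.repeat(times, nr),
                        "replicate": np.tile(np.arange(nr), nt),
                        "intensity": arr.ravel(),
                    }
                )
            )
    nc = spec.negctrl_level * _lognormal_factors(rng, spec.noise_cv, (nt, nr))
    rows.append(
        pd.DataFrame(
            {
                "molecule_id": NEGCTRL_ID,
                "channel": "negative_control",
                "time_min": np.repeat(times, nr),
                "replicate": np.tile(np.arange(nr), nt),
                "intensity": nc.ravel(),
            }
        )
    )
    records = pd.concat(rows, ignore_index=True)
    return PhosphoArrayDataset(records, condition=spec.condition)


def ground_truth(spec: DatasetSpec) -> dict[str, tuple[float, float]]:
    """Closed-form (tau_true, beta_true) per molecule.

    For the triangular pulse the time-averaged fold change over one signal
    duration is 1 + A/(2*baseline), hence
    beta_true = ln(1 + A/(2*baseline)) / tau_true. Inactive molecules have
    no defined duration and zero rate: (nan, 0).
    """
    out = {}
    for mol in spec.molecules:
        if not mol.active:
            out[mol.molecule_id] = (float("nan"), 0.0)
        else:
            ratio = 1.0 + mol.pulse_amplitude / (2.0 * mol.baseline_intensity)
            out[mol.molecule_id] = (mol.tau_true, float(np.log(ratio) / mol.tau_true))
    return out


def write_ground_truth(spec: DatasetSpec, path) -> None:
    """JSON sidecar with the generator's closed-form truth."""
    gt = {
        m: {"tau_true": t if np.isfinite(t) else None, "beta_true": b}
        for m, (t, b) in ground_truth(spec).items()
    }
    with open(path, "w") as fh:
        json.dump({"condition": spec.condition, "seed": spec.seed, "truth": gt}, fh, indent=2)


# ---------------------------------------------------------------------------
# Default study panel
# ---------------------------------------------------------------------------

def _pulse_for(beta: float, tau: float, baseline: float = 100.0, t_peak: float = 15.0) -> MoleculeSpec:
    """Invert the closed form: amplitude giving target STR beta over tau."""
    a = 2.0 * baseline * (np.exp(beta * tau) - 1.0)
    return MoleculeSpec("", baseline, a, t_peak, tau)


#: EGF-responsive MAPK panel: the proliferative Src-Raf1-MEK1-ERK1 (SRME)
#: cascade, the stress-responsive ASK1-MKK4/MKK3-JNK (AMMJ) cascade with its
#: downstream HSF1-Tau branch, and unrelated bystander molecules.
PANEL_MOLECULES = (
    "Src", "Raf1", "MEK1", "ERK1", "p53",
    "ASK1", "MKK4", "MKK3", "JNK", "HSF1", "Tau",
    "hsp27", "c-Jun", "ATF2",
    "EGFR", "Akt", "p38", "STAT3", "mTOR",
)

_SRME = ("Src", "Raf1", "MEK1", "ERK1")
_AMMJ = ("ASK1", "MKK4", "MKK3", "JNK")


def default_panel(stressed: bool = False, seed: int = 0) -> DatasetSpec:
    """The study's default 19-molecule panel under one condition.

    Without stress only the SRME cascade responds to EGF (common STR
    0.08 min^-1 over a 45-min pulse, i.e. 3.6 nats of information gain and
    a ~37-fold peak phosphorylation — A431 cells overexpress EGFR, and
    serum-starved EGF-stimulated cells show phospho-fold inductions of tens);
    p53 responds with a distinct, slower rate. Under starvation stress the
    AMMJ cascade plus its HSF1-Tau extension activate as well (common STR
    0.12 min^-1 over a 30-min pulse), with weaker stress responses in hsp27,
    c-Jun and ATF2. Every active molecule carries at least ~1.2 nats of
    information gain, keeping even the weakest responder several noise
    sigmas above the default detection threshold. All remaining molecules
    stay at baseline.
    """
    active: dict[str, tuple[float, float]] = {m: (0.08, 45.0) for m in _SRME}
    active["p53"] = (0.027, 45.0)
    if stressed:
        for m in (*_AMMJ, "HSF1", "Tau"):
            active[m] = (0.12, 30.0)
        active["hsp27"] = (0.04, 30.0)
        active["c-Jun"] = (0.04, 30.0)
        active["ATF2"] = (0.04, 30.0)

    molecules = []
    for name in PANEL_MOLECULES:
        if name in active:
            beta, tau = active[name]
            proto = _pulse_for(beta, tau)
            molecules.append(
                MoleculeSpec(name, proto.baseline_intensity, proto.pulse_amplitude,
                             proto.t_peak, proto.tau_true)
            )
        else:
            molecules.append(MoleculeSpec(name))
    return DatasetSpec(
        molecules=tuple(molecules),
        condition="stressed" if stressed else "non_stressed",
        seed=seed,
    )
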