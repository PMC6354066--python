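"""Synthetic cohort generator.

Emulates a three-group mouse study (wild-type controls, untreated transgenics
with progressive forebrain atrophy, and drug-treated transgenics with
attenuated atrophy) scanned longitudinally "in vivo" at three ages plus one
terminal "ex vivo" acquisition.

Per structure, the true volume trajectory follows a linear mixed-effects
generative model::

    V(t) = beta0 + beta1*t + beta2*g + beta3*t*g + b1 + b2*t + eps

with ``g`` a per-group severity code (wild-type 0, treated 0.5, untreated 1),
``b1 ~ N(0, sigma_b1^2)`` a per-subject intercept, ``b2 ~ N(0, sigma_b2^2)``
a per-subject slope, and ``eps ~ N(0, sigma_eps^2)`` a per-scan residual.
Ex vivo volumes are the terminal in vivo volumes scaled by tissue-class
factors: gray matter shrinks, white matter expands, ventricular CSF collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StructureDef",
    "ModalityParams",
    "CohortSpec",
    "SubjectTrajectory",
    "GROUPS",
    "default_structures",
    "default_cohort_spec",
    "make_cohort",
    "true_volume",
    "apply_exvivo_effect",
]

#: Group codes: severity of the tau phenotype entering the generative model.
GROUPS = {"WT": 0.0, "TT": 0.5, "UT": 1.0}

VOLUME_FLOOR_MM3 = 1e-3  # keeps percentage volume difference defined

TISSUES = ("GM", "WM", "CSF")


class SpecValidationError(ValueError):
    """A cohort-spec field violates its invariant."""


@dataclass(frozen=True)
class StructureDef:
    """One catalog entry: a named structure and its generative parameters.

    ``beta0`` is the baseline (wild-type, age-0 intercept) volume in mm^3;
    ``beta1`` the common age slope (mm^3/month); ``beta2``/``beta3`` the
    severity offset (mm^3) and severity-by-age interaction (mm^3/month);
    ``sigma_b1``/``sigma_b2`` the random intercept/slope SDs; ``sigma_eps``
    the per-scan residual SD.
    """

    name: str
    tissue: str
    bilateral: bool
    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    sigma_b1: float = 0.0
    sigma_b2: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise SpecValidationError(
                f"structure {self.name!r}: tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.beta0 <= 0:
            raise SpecValidationError(
                f"structure {self.name!r}: baseline volume beta0 must be > 0, got {self.beta0}")
        for fld in ("sigma_b1", "sigma_b2", "sigma_eps"):
            if getattr(self, fld) < 0:
                raise SpecValidationError(f"structure {self.name!r}: {fld} must be >= 0")


@dataclass(frozen=True)
class ModalityParams:
    """Acquisition stand-in: voxel spacing, tissue intensity means, noise."""

    spacing_mm: float
    grid_shape: tuple[int, int, int]
    intensity: dict = field(default_factory=dict)  # tissue/background -> mean
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise SpecValidationError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if self.noise_sd < 0:
            raise SpecValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(n < 4 for n in self.grid_shape):
            raise SpecValidationError(f"grid_shape axes must be >= 4, got {self.grid_shape}")


def default_structures() -> list[StructureDef]:
    """Realistic adult-mouse structure catalog (volumes in mm^3).

    Baselines approximate literature values for the major parcellated
    structures; atrophy enters through the severity interaction ``beta3``
    (gray matter shrinks with disease, ventricles expand), with small
    common growth ``beta1`` and ~1-3% per-subject variability.
    """
    rows = [
        # name, tissue, bilateral, beta0, beta1, beta3 (per severity, mm^3/month)
        ("neocortex",           "GM", True, 110.0, 0.30, -1.80),
        ("cerebellum",          "GM", False, 55.0, 0.15, -0.25),
        ("thalamus",            "GM", True,  38.0, 0.10, -0.45),
        ("olfactory_bulb",      "GM", True,  25.0, 0.08, -0.30),
        ("hippocampus",         "GM", True,  22.0, 0.06, -0.55),
        ("caudate_putamen",     "GM", True,  22.0, 0.06, -0.35),
        ("hypothalamus",        "GM", True,  12.0, 0.03, -0.12),
        ("internal_capsule",    "WM", True,   8.0, 0.02, -0.05),
        ("ventricles",          "CSF", True,  5.0, 0.02,  0.55),
        ("fimbria",             "WM", True,   5.0, 0.01, -0.04),
        ("anterior_commissure", "WM", False,  2.0, 0.00, -0.01),
    ]
    out = []
    for name, tissue, bilat, b0, b1, b3 in rows:
        out.append(StructureDef(
            name=name, tissue=tissue, bilateral=bilat,
            beta0=b0, beta1=b1, beta2=0.0, beta3=b3,
            sigma_b1=0.02 * b0, sigma_b2=0.01 * b0, sigma_eps=0.01 * b0))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Full description of the synthetic study cohort."""

    group_sizes: dict = field(
        default_factory=lambda: {"WT": 8, "UT": 10, "TT": 7})
    timepoints: tuple[float, ...] = (4.5, 5.5, 7.5)  # months
    structures: tuple[StructureDef, ...] = field(
        default_factory=lambda: tuple(default_structures()))
    group_codes: dict = field(default_factory=lambda: dict(GROUPS))
    # tissue-class multipliers applied in vivo -> ex vivo; optional per-group
    # overrides as {"UT": {"GM": ...}, ...}
    exvivo_factors: dict = field(
        default_factory=lambda: {"GM": 0.92, "WM": 1.08, "CSF": 0.03})
    exvivo_group_factors: dict = field(default_factory=dict)
    invivo: ModalityParams = field(default_factory=lambda: ModalityParams(
        spacing_mm=0.15, grid_shape=(78, 78, 78),
        intensity={"GM": 100.0, "WM": 70.0, "CSF": 130.0, "background": 10.0},
        noise_sd=30.0))
    exvivo: ModalityParams = field(default_factory=lambda: ModalityParams(
        spacing_mm=0.04, grid_shape=(292, 292, 292),
        intensity={"GM": 100.0, "WM": 70.0, "CSF": 130.0, "background": 10.0},
        noise_sd=12.0))
    gradient_drift_per_month: float = 0.0  # fractional linear-dimension drift
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in self.group_codes:
                raise SpecValidationError(f"group_sizes: unknown group {g!r}")
            if int(n) != n or n < 0:
                raise SpecValidationError(f"group_sizes[{g!r}] must be a count >= 0, got {n}")
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) < 1 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise SpecValidationError(f"timepoints must be strictly increasing, got {tp}")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise SpecValidationError("structures: duplicate structure names")
        for tissue, f in self.exvivo_factors.items():
            if tissue not in TISSUES:
                raise SpecValidationError(f"exvivo_factors: unknown tissue {tissue!r}")
            if f <= 0:
                raise SpecValidationError(f"exvivo_factors[{tissue!r}] must be > 0, got {f}")
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "structures", tuple(self.structures))

    @property
    def structure_names(self) -> list[str]:
        return [s.name for s in self.structures]

    def structure(self, name: str) -> StructureDef:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"unknown structure {name!r}")

    def replace(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubjectTrajectory:
    """Realized per-subject volumes and random effects."""

    subject_id: str
    group: str
    group_code: float
    timepoints: tuple[float, ...]
    b1: dict  # structure -> mm^3
    b2: dict  # structure -> mm^3/month
    invivo_volumes: tuple[dict, ...]  # one dict per timepoint (with residual noise)
    exvivo_volumes: dict  # terminal, after ex vivo tissue change
    spec: CohortSpec = field(repr=False, default=None)

    def __post_init__(self):
        if len(self.invivo_volumes) != len(self.timepoints):
            raise ValueError("one in vivo volume dict required per timepoint")
        for vols in self.invivo_volumes:
            for name, v in vols.items():
                if v <= 0:
                    raise ValueError(f"in vivo volume for {name!r} must be > 0")
        for name, v in self.exvivo_volumes.items():
            if v < 0:
                raise ValueError(f"ex vivo volume for {name!r} must be >= 0")


def _subject_rng(seed: int, group: str, index: int) -> np.random.Generator:
    # stream keyed by (seed, group, within-group index): adding subjects or
    # groups never reshuffles existing subjects
    gcode = sum(ord(c) * 257 ** i for i, c in enumerate(group)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed), gcode, int(index))))


def true_volume(trajectory: SubjectTrajectory, structure: str, time: float) -> float:
    """Noiseless generative volume of ``structure`` at age ``time`` months."""
    spec = trajectory.spec
    if spec is None or structure not in trajectory.b1:
        raise KeyError(f"unknown structure {structure!r}")
    s = spec.structure(structure)
    g = trajectory.group_code
    v = (s.beta0 + s.beta1 * time + s.beta2 * g + s.beta3 * time * g
         + trajectory.b1[structure] + trajectory.b2[structure] * time)
    return max(v, VOLUME_FLOOR_MM3)


def apply_exvivo_effect(volumes: dict, spec: CohortSpec, group: str) -> dict:
    """Scale in vivo volumes by tissue-class (x group) ex vivo change factors.

    Defaults shrink gray matter, expand white matter and collapse CSF spaces.
    Volumes are floored at a small positive value so downstream percentage
    differences stay defined.
    """
    factors = dict(spec.exvivo_factors)
    factors.update(spec.exvivo_group_factors.get(group, {}))
    out = {}
    for name, v in volumes.items():
        if v <= 0:
            raise ValueError(f"in vivo volume for {name!r} must be > 0")
        tissue = spec.structure(name).tissue
        if tissue not in factors:
            raise SpecValidationError(f"no ex vivo factor configured for tissue {tissue!r}")
        out[name] = max(v * factors[tissue], VOLUME_FLOOR_MM3)
    return out


def make_cohort(spec: CohortSpec, seed: int | None = None) -> list[SubjectTrajectory]:
    """Draw one trajectory per subject, deterministically given the seed."""
    seed = spec.seed if seed is None else int(seed)
    times = np.asarray(spec.timepoints)
    cohort: list[SubjectTrajectory] = []
    for group in spec.group_sizes:  # dict order: stable, group-keyed streams
        g = spec.group_codes[group]
        for i in range(int(spec.group_sizes[group])):
            rng = _subject_rng(seed, group, i)
            b1, b2 = {}, {}
            per_tp = [dict() for _ in times]
            for s in spec.structures:
                b1[s.name] = rng.normal(0.0, s.sigma_b1) if s.sigma_b1 > 0 else 0.0
                b2[s.name] = rng.normal(0.0, s.sigma_b2) if s.sigma_b2 > 0 else 0.0
                eps = rng.normal(0.0, s.sigma_eps, size=len(times)) if s.sigma_eps > 0 \
                    else np.zeros(len(times))
                mean = (s.beta0 + s.beta1 * times + s.beta2 * g + s.beta3 * times * g
                        + b1[s.name] + b2[s.name] * times)
                vols = np.maximum(mean + eps, VOLUME_FLOOR_MM3)
                for k in range(len(times)):
                    per_tp[k][s.name] = float(vols[k])
            traj = SubjectTrajectory(
                subject_id=f"{group}{i + 1:02d}", group=group, group_code=g,
                timepoints=spec.timepoints, b1=b1, b2=b2,
                invivo_volumes=tuple(per_tp),
                exvivo_volumes=apply_exvivo_effect(per_tp[-1], spec, group),
                spec=spec)
            cohort.append(traj)
    return cohort


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study's stated cohort: 8 WT + 10 untreated + 7 treated, ages
    4.5/5.5/7.5 months, 150 um in vivo vs 40 um ex vivo."""
    return CohortSpec(**overrides)
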