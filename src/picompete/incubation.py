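"""Synthetic nutrient-amendment incubation datasets.

Emulates deck-board microcosm bioassays: ambient surface water with
nanomolar N, bottled in replicate, amended with ~100 nM of a single N
substrate (or 10 nM P), and sampled daily for flow-cytometric cell
counts and nanomolar nutrient chemistry.  Grazers are absent by
construction, mirroring prefiltration of the inoculum, so abundance
changes reflect growth and mortality only.

Counts carry multiplicative log-normal observation noise (FCM counts
span orders of magnitude); nutrient measurements are censored at the
assay detection limits (3 nM for NO3-+NO2-, 6 nM for NH4+, 3 nM for
SRP) and reported at the limit when below it.

Urea and phosphate treatments can be generated as design placeholders
(their abundance dynamics follow the control, since the two-nutrient
model does not represent them); they are marked unmodelled and excluded
from fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ModelState, Trajectory, integrate
from .exceptions import ConfigurationError, DataError, StateError
from .params import CommunityConfig, InitialConditions

__all__ = [
    "DETECTION_LIMITS", "TreatmentSpec", "IncubationDesign",
    "IncubationDataset", "censor", "generate_incubation",
    "treatment_initial_state",
]

DETECTION_LIMITS = {"no3": 3.0, "nh4": 6.0, "srp": 3.0}

# treatment name -> (amended state variable or None, default amendment nM)
_TREATMENTS = {
    "control": (None, 0.0),
    "add_no3": ("no3", 100.0),
    "add_nh4": ("nh4", 100.0),
    "add_urea": (None, 100.0),   # generated, not modelled
    "add_p": (None, 10.0),       # generated, not modelled
}
MODELED_TREATMENTS = ("control", "add_no3", "add_nh4")


@dataclass(frozen=True)
class TreatmentSpec:
    name: str
    amendment: float

    def __post_init__(self) -> None:
        if self.name not in _TREATMENTS:
            raise ConfigurationError(
                f"unknown treatment {self.name!r}; expected one of {sorted(_TREATMENTS)}")
        if self.amendment < 0:
            raise ConfigurationError("amendment must be >= 0")

    @property
    def modeled(self) -> bool:
        return self.name in MODELED_TREATMENTS


@dataclass(frozen=True)
class IncubationDesign:
    """Design of one bioassay: treatments, duration, replication, limits."""

    treatments: tuple = ("control", "add_no3", "add_nh4")
    amendment_n: float = 100.0
    amendment_p: float = 10.0
    duration: float = 3.0
    n_replicates: int = 3
    detection_limits: dict = field(default_factory=lambda: dict(DETECTION_LIMITS))

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ConfigurationError("duration must be >= 1 day")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.amendment_n < 0 or self.amendment_p < 0:
            raise ConfigurationError("amendments must be >= 0")
        object.__setattr__(self, "treatments", tuple(self.treatments))
        self.specs  # validates treatment names

    def _spec(self, name: str) -> TreatmentSpec:
        default = _TREATMENTS.get(name, (None, 0.0))[1]
        if name in ("add_no3", "add_nh4", "add_urea"):
            default = self.amendment_n
        elif name == "add_p":
            default = self.amendment_p
        return TreatmentSpec(name=name, amendment=default if name != "control" else 0.0)

    @property
    def specs(self) -> tuple[TreatmentSpec, ...]:
        return tuple(self._spec(t) for t in self.treatments)

    @property
    def sampling_days(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5, 1.0)


def censor(conc: float, limit: float) -> tuple[float, bool]:
    """Apply a detection limit: values below it are reported *at* the limit
    with a below-detection flag (boundary inclusive: conc == limit is a
    valid detection)."""
    if limit <= 0:
        raise ConfigurationError(f"detection limit must be > 0, got {limit}")
    if conc < 0:
        raise StateError(f"concentration must be >= 0, got {conc}")
    if conc < limit:
        return limit, True
    return float(conc), False


def treatment_initial_state(init: InitialConditions, spec: TreatmentSpec) -> ModelState:
    """Initial bottle state: ambient conditions plus the amendment."""
    no3, nh4 = init.no3, init.nh4
    if spec.name == "add_no3":
        no3 += spec.amendment
    elif spec.name == "add_nh4":
        nh4 += spec.amendment
    return ModelState(x_pro=init.x_pro, x_syn=init.x_syn, no3=no3, nh4=nh4)


_ABUND_COLS = ["treatment", "replicate", "day", "genus", "abundance"]
_NUTR_COLS = ["treatment", "replicate", "day", "nutrient", "concentration",
              "below_detection"]


@dataclass
class IncubationDataset:
    """Replicated incubation observations.

    ``abundance``: rows (treatment, replicate, day, genus, abundance) with
    abundance in cells L^-1 and genus in {pro, syn}.
    ``nutrients``: rows (treatment, replicate, day, nutrient, concentration,
    below_detection) in nmol L^-1; flagged rows are reported at the
    detection limit.
    ``provenance``: generating parameters and seed, or ``{"source": "observed"}``.
    """

    abundance: pd.DataFrame
    nutrients: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "observed"})
    design: IncubationDesign = field(default_factory=IncubationDesign)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for df, cols, label in ((self.abundance, _ABUND_COLS, "abundance"),
                                (self.nutrients, _NUTR_COLS, "nutrients")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise DataError(f"{label} table missing columns {missing}")
        if len(self.abundance) and (self.abundance["abundance"] <= 0).any():
            raise DataError("abundances must be > 0")
        if len(self.nutrients) and (self.nutrients["concentration"] < 0).any():
            raise DataError("concentrations must be >= 0")
        key = ["treatment", "replicate", "day", "genus"]
        if self.abundance.duplicated(subset=key).any():
            dup = self.abundance[self.abundance.duplicated(subset=key)]
            raise DataError(
                f"duplicate design rows in abundance table at index {list(dup.index)}")

    @property
    def treatments(self) -> list[str]:
        return sorted(self.abundance["treatment"].unique())

    def treatment_means(self) -> pd.DataFrame:
        """Replicate-mean log10 abundance per treatment/day/genus."""
        df = self.abundance.copy()
        df["log10_abundance"] = np.log10(df["abundance"])
        return (df.groupby(["treatment", "day", "genus"], as_index=False)
                  ["log10_abundance"].mean())

    def to_dataframe(self) -> pd.DataFrame:
        a = self.abundance.copy()
        a["variable"] = a["genus"]
        a["value"] = a["abundance"]
        a["below_detection"] = False
        n = self.nutrients.copy()
        n["variable"] = n["nutrient"]
        n["value"] = n["concentration"]
        cols = ["treatment", "replicate", "day", "variable", "value",
                "below_detection"]
        return pd.concat([a[cols], n[cols]], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       design: IncubationDesign | None = None,
                       provenance: dict | None = None) -> "IncubationDataset":
        required = {"treatment", "replicate", "day", "variable", "value"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"dataset table missing columns {sorted(missing)}")
        if "below_detection" not in df.columns:
            df = df.assign(below_detection=False)
        is_genus = df["variable"].isin(["pro", "syn"])
        a = df[is_genus].rename(columns={"variable": "genus", "value": "abundance"})
        n = df[~is_genus].rename(columns={"variable": "nutrient",
                                          "value": "concentration"})
        return cls(abundance=a[_ABUND_COLS].reset_index(drop=True),
                   nutrients=n[_NUTR_COLS].reset_index(drop=True),
                   provenance=provenance or {"source": "observed"},
                   design=design or IncubationDesign())

    @classmethod
    def from_csv(cls, path, design: IncubationDesign | None = None) -> "IncubationDataset":
        return cls.from_dataframe(pd.read_csv(path), design=design)


def generate_incubation(cfg: CommunityConfig,
                        design: IncubationDesign | None = None,
                        init: InitialConditions | None = None,
                        sigma_log10: float = 0.05,
                        seed: int | None = 0) -> IncubationDataset:
    """Simulate a replicated incubation experiment.

    Per treatment the model is integrated from ambient initial conditions
    plus the amendment; replicate cell counts are the model truth times
    ``10**Normal(0, sigma_log10)``, and nutrient values are the model truth
    censored at the detection limits.  Deterministic for a fixed seed;
    ``sigma_log10 = 0`` returns the noise-free truth.
    """
    if design is None:
        design = IncubationDesign()
    if init is None:
        init = InitialConditions()
    if sigma_log10 < 0:
        raise ConfigurationError("sigma_log10 must be >= 0")
    rng = np.random.default_rng(seed)
    days = design.sampling_days

    control_traj: Trajectory | None = None
    abund_rows, nutr_rows = [], []
    for spec in design.specs:
        if spec.modeled:
            traj = integrate(cfg, treatment_initial_state(init, spec),
                             t_end=float(days[-1]), dt_out=1.0)
        else:
            # unmodelled placeholder: population truth follows the control
            if control_traj is None:
                control_traj = integrate(
                    cfg, treatment_initial_state(init, TreatmentSpec("control", 0.0)),
                    t_end=float(days[-1]), dt_out=1.0)
            traj = control_traj
        if spec.name == "control":
            control_traj = traj
        states = {float(t): traj.state_at(float(t)) for t in days}
        for rep in range(1, design.n_replicates + 1):
            for day in days:
                st = states[float(day)]
                for genus, truth in (("pro", st.x_pro), ("syn", st.x_syn)):
                    noise = 10 ** rng.normal(0.0, sigma_log10) if sigma_log10 > 0 else 1.0
                    abund_rows.append((spec.name, rep, float(day), genus,
                                       truth * noise))
                for nutrient, truth in (("no3", st.no3), ("nh4", st.nh4)):
                    value, flag = censor(truth, design.detection_limits[nutrient])
                    nutr_rows.append((spec.name, rep, float(day), nutrient,
                                      value, flag))
                if spec.name == "add_p":
                    value, flag = censor(spec.amendment,
                                         design.detection_limits["srp"])
                    nutr_rows.append((spec.name, rep, float(day), "srp",
                                      value, flag))

    abundance = pd.DataFrame(abund_rows, columns=_ABUND_COLS)
    nutrients = pd.DataFrame(nutr_rows, columns=_NUTR_COLS)
    provenance = {
        "source": "synthetic",
        "seed": seed,
        "sigma_log10": sigma_log10,
        "parameters": {
            "pro": cfg.pro.__dict__, "syn": cfg.syn.__dict__,
            "s_no3": cfg.s_no3, "s_nh4": cfg.s_nh4,
        },
        "initial": init.__dict__,
    }
    return IncubationDataset(abundance=abundance, nutrients=nutrients,
                             provenance=provenance, design=design)
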