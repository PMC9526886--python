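"""Event-level cytometry: reading samples, lymphocyte gating, geometric means.

The whole analysis rests on one per-sample summary statistic — the geometric
mean fluorescence intensity of the γH2AX (FITC) channel — computed after an
optional scatter gate that removes debris. Per-event fluorescence is treated
as log-normal, for which the geometric mean is the natural location
statistic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcsio

#: Channel roles and the header-name patterns used to resolve them when no
#: explicit mapping is configured. Matching is case-insensitive and ignores
#: the "-A"/"-H"/"-W" pulse-statistic suffix.
_ROLE_PATTERNS: dict[str, tuple[str, ...]] = {
    "scatter1": ("FSC",),
    "scatter2": ("SSC",),
    "gamma_h2ax": ("FITC", "FL1", "GH2AX", "H2AX"),
    "dna": ("PI", "FL2", "FL3"),
}

_FILENAME_RE = re.compile(
    r"^(?P<pid>[A-Za-z0-9-]+)_(?P<dose>[0-9]+(?:\.[0-9]+)?)Gy_"
    r"(?P<time>[0-9]+(?:\.[0-9]+)?)h\.(?:csv|fcs)$",
    re.IGNORECASE,
)


@dataclass
class EventSample:
    """One tube: per-event scatter and fluorescence values with their labels.

    ``events`` holds one row per event in acquisition order; ``channels``
    maps roles (scatter1, scatter2, gamma_h2ax, dna) to column names.
    """

    patient_id: str
    dose: float
    timepoint: float
    events: pd.DataFrame
    channels: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"negative dose {self.dose} Gy")
        if self.timepoint <= 0:
            raise ValueError(f"nonpositive timepoint {self.timepoint} h")
        if len(self.events) == 0:
            raise ValueError(f"{self.source or self.patient_id}: zero events")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def intensity(self, role: str = "gamma_h2ax") -> np.ndarray:
        col = self.channels.get(role)
        if col is None:
            raise KeyError(f"no channel mapped to role {role!r} in {self.source or self.patient_id}")
        return self.events[col].to_numpy(dtype=float)


@dataclass
class GateSpec:
    """Declarative scatter gate.

    mode "none" is the identity; "rectangle" keeps events with scatter1 and
    scatter2 inside the closed ranges; "ellipse" keeps events inside the
    axis-aligned ellipse inscribed in that bounding box.
    """

    mode: str = "none"
    scatter1_range: tuple[float, float] | None = None
    scatter2_range: tuple[float, float] | None = None
    min_events_after_gate: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("none", "rectangle", "ellipse"):
            raise ValueError(f"unknown gate mode {self.mode!r}")
        if self.mode != "none":
            for name, rng in (("scatter1", self.scatter1_range), ("scatter2", self.scatter2_range)):
                if rng is None:
                    raise ValueError(f"gate mode {self.mode!r} requires {name}_range")
                lo, hi = rng
                if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
                    raise ValueError(f"{name}_range must be finite and ordered, got {rng}")


@dataclass
class GatedStatistic:
    """Geometric-mean summary of one gated sample."""

    patient_id: str
    dose: float
    timepoint: float
    n_events_total: int
    n_events_gated: int
    geometric_mean: float
    n_excluded_nonpositive: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_events_gated <= self.n_events_total:
            raise ValueError("gated event count must be in (0, total]")
        if not self.geometric_mean > 0:
            raise ValueError("geometric mean must be positive")


def resolve_channels(columns: list[str], overrides: dict[str, str] | None = None) -> dict[str, str]:
    """Map channel roles to column names.

    Explicit ``overrides`` (role -> column name) win; remaining roles are
    resolved by name patterns. An ambiguous pattern match is an error, a
    missing optional role (dna) is not.
    """
    mapping: dict[str, str] = {}
    for role, col in (overrides or {}).items():
        if role not in _ROLE_PATTERNS:
            raise KeyError(f"unknown channel role {role!r}")
        if col not in columns:
            raise KeyError(f"configured channel {col!r} for role {role!r} not in file columns {columns}")
        mapping[role] = col
    for role, patterns in _ROLE_PATTERNS.items():
        if role in mapping:
            continue
        hits = [c for c in columns if _normalize(c) in patterns and c not in mapping.values()]
        if len(hits) > 1:
            raise ValueError(f"ambiguous channel mapping for role {role!r}: {hits}")
        if hits:
            mapping[role] = hits[0]
    for required in ("gamma_h2ax",):
        if required not in mapping:
            raise ValueError(f"could not resolve required channel role {required!r} from columns {columns}")
    return mapping


def _normalize(name: str) -> str:
    return re.sub(r"-[AHW]$", "", name.strip().upper())


def parse_sample_filename(name: str) -> tuple[str, float, float]:
    """Extract (patient_id, dose Gy, timepoint h) from ``P01_2Gy_0.5h.csv``."""
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"cannot parse sample metadata from filename {name!r}")
    return m.group("pid"), float(m.group("dose")), float(m.group("time"))


def read_events(
    path: str | Path,
    format: str | None = None,
    channels: dict[str, str] | None = None,
    patient_id: str | None = None,
    dose: float | None = None,
    timepoint: float | None = None,
) -> EventSample:
    """Read one sample from CSV (header ``FSC,SSC,FITC,PI``) or FCS.

    Sample labels default to the ``P{patient}_{dose}Gy_{time}h`` filename
    convention; pass them explicitly for files named otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        events = pd.read_csv(path)
        if events.shape[0] == 0:
            raise ValueError(f"{path}: zero events")
        events = events.astype(float)
    elif fmt == "fcs":
        _, events = fcsio.read_fcs(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if patient_id is None or dose is None or timepoint is None:
        pid, d, t = parse_sample_filename(path.name)
        patient_id = patient_id if patient_id is not None else pid
        dose = dose if dose is not None else d
        timepoint = timepoint if timepoint is not None else t
    mapping = resolve_channels(list(events.columns), channels)
    return EventSample(patient_id, dose, timepoint, events, mapping, source=str(path))


def apply_gate(sample: EventSample, gate: GateSpec) -> EventSample:
    """Return the sample restricted to events inside the gate."""
    if gate.mode == "none":
        return sample
    s1 = sample.intensity("scatter1")
    s2 = sample.intensity("scatter2")
    lo1, hi1 = gate.scatter1_range
    lo2, hi2 = gate.scatter2_range
    if gate.mode == "rectangle":
        keep = (s1 >= lo1) & (s1 <= hi1) & (s2 >= lo2) & (s2 <= hi2)
    else:  # ellipse inscribed in the bounding box
        cx, rx = (lo1 + hi1) / 2.0, (hi1 - lo1) / 2.0
        cy, ry = (lo2 + hi2) / 2.0, (hi2 - lo2) / 2.0
        keep = ((s1 - cx) / rx) ** 2 + ((s2 - cy) / ry) ** 2 <= 1.0
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError(f"{sample.source or sample.patient_id}: gate removed all {sample.n_events} events")
    if n_kept < gate.min_events_after_gate:
        raise ValueError(
            f"{sample.source or sample.patient_id}: only {n_kept} events after gate "
            f"(minimum {gate.min_events_after_gate})"
        )
    return replace(sample, events=sample.events.loc[keep].reset_index(drop=True))


def geometric_mean(
    intensities: np.ndarray, nonpositive_policy: str = "exclude", epsilon: float = 1e-6
) -> tuple[float, int]:
    """exp(mean(ln x)) with an explicit policy for nonpositive values.

    Instrument compensation can push a few events to zero or below, where the
    log is undefined. Policy "exclude" drops them (returning the count);
    "shift_epsilon" replaces them with ``epsilon`` so fixtures with planted
    zeros stay usable.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no intensities given")
    nonpos = ~(x > 0)
    n_nonpos = int(nonpos.sum())
    if nonpositive_policy == "exclude":
        x = x[~nonpos]
    elif nonpositive_policy == "shift_epsilon":
        x = np.where(nonpos, epsilon, x)
    else:
        raise ValueError(f"unknown nonpositive_policy {nonpositive_policy!r}")
    if x.size == 0:
        raise ValueError(f"no usable events: all {n_nonpos} intensities nonpositive")
    return float(np.exp(np.mean(np.log(x)))), n_nonpos


def gated_statistic(
    sample: EventSample, gate: GateSpec | None = None, nonpositive_policy: str = "exclude"
) -> GatedStatistic:
    """Gate a sample and summarize its γH2AX channel as a geometric mean."""
    gated = apply_gate(sample, gate) if gate is not None else sample
    gm, n_excl = geometric_mean(gated.intensity("gamma_h2ax"), nonpositive_policy)
    return GatedStatistic(
        patient_id=sample.patient_id,
        dose=sample.dose,
        timepoint=sample.timepoint,
        n_events_total=sample.n_events,
        n_events_gated=gated.n_events,
        geometric_mean=gm,
        n_excluded_nonpositive=n_excl,
    )
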