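"""Sliding-window extremum features on component time courses.

A feature template (start, end, window size, step, extremum type,
return type) is expanded into concrete features: the window starts at
the template start, slides by the step while it still fits before the
end point, and each placement yields either the extremal amplitude (uV)
or its latency (ms, stimulus-relative) of the component time course at
one electrode.  The subjects x features matrix these produce is the
classifier's input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN, MAX = "min", "max"
AMPLITUDE, LATENCY = "amplitude", "latency"

#: template settings of the reference adult ADHD / control analysis:
#: 0-600 ms range, 100 ms window +/-25% and +/-50%, 4 ms step,
#: both extremum types crossed with both return types.
REFERENCE_WINDOW_SIZES_MS = (50.0, 75.0, 100.0, 125.0, 150.0)
REFERENCE_STEP_MS = 4.0
REFERENCE_RANGE_MS = (0.0, 600.0)

#: the five windows the reference analysis ended up selecting, all
#: latency-of-minimum features: (component label, t0, t1) in ms.
REFERENCE_SELECTED_WINDOWS = (
    ("BA6_novelty", 112.0, 160.0),
    ("BA18", 292.0, 364.0),
    ("BA25", 480.0, 528.0),
    ("BA5", 488.0, 588.0),
    ("BA5", 440.0, 540.0),
)

#: reference electrode per component, from amplitude prominence
REFERENCE_CHANNEL_MAP = {
    "BA18": "O1",
    "BA39left": "T5",
    "BA39right": "T6",
    "BA5": "Pz",
    "BA6": "Cz",
    "BA25": "Cz",
    "BA6_novelty": "Cz",
}


@dataclass(frozen=True)
class FeatureTemplate:
    """Parametric description of a family of sliding-window features."""

    start_ms: float
    end_ms: float
    window_ms: float
    step_ms: float
    extremum: str = MIN
    returns: str = LATENCY

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("start_ms must be < end_ms")
        if not 0 < self.window_ms <= self.end_ms - self.start_ms:
            raise ValueError("window_ms must be in (0, end_ms - start_ms]")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.extremum not in (MIN, MAX):
            raise ValueError(f"extremum must be '{MIN}' or '{MAX}'")
        if self.returns not in (AMPLITUDE, LATENCY):
            raise ValueError(f"returns must be '{AMPLITUDE}' or '{LATENCY}'")

    @property
    def n_windows(self) -> int:
        """Closed form: floor((end - window - start) / step) + 1."""
        return int(np.floor((self.end_ms - self.window_ms - self.start_ms) / self.step_ms)) + 1


@dataclass(frozen=True)
class FeatureSpec:
    """One concrete feature: a window on one component at one electrode."""

    component: str
    channel: str
    t0_ms: float
    t1_ms: float
    extremum: str
    returns: str

    def __post_init__(self) -> None:
        if not self.t0_ms < self.t1_ms:
            raise ValueError("t0_ms must be < t1_ms")

    @property
    def feature_id(self) -> str:
        return f"{self.component}_{self.channel}_{self.extremum}_{self.returns}_{self.t0_ms:g}_{self.t1_ms:g}"


def enumerate_features(
    template: FeatureTemplate,
    components,
    channel_map: dict[str, str] | None = None,
) -> list[FeatureSpec]:
    """Instantiate a template over components, in deterministic order
    (component order, then window start).

    ``components`` is a list of component names, or of (name, channel)
    pairs; names alone require ``channel_map``.
    """
    specs = []
    for comp in components:
        if isinstance(comp, tuple):
            name, channel = comp
        else:
            name = comp
            if channel_map is None or name not in channel_map:
                raise KeyError(f"no channel mapped for component {name!r}")
            channel = channel_map[name]
        for j in range(template.n_windows):
            t0 = template.start_ms + j * template.step_ms
            specs.append(
                FeatureSpec(
                    component=name,
                    channel=channel,
                    t0_ms=t0,
                    t1_ms=t0 + template.window_ms,
                    extremum=template.extremum,
                    returns=template.returns,
                )
            )
    return specs


def reference_templates(
    window_sizes=REFERENCE_WINDOW_SIZES_MS,
    step_ms=REFERENCE_STEP_MS,
    time_range=REFERENCE_RANGE_MS,
) -> list[FeatureTemplate]:
    """All extremum/return combinations over the given window sizes."""
    return [
        FeatureTemplate(time_range[0], time_range[1], w, step_ms, extremum=e, returns=r)
        for w in window_sizes
        for e in (MIN, MAX)
        for r in (AMPLITUDE, LATENCY)
    ]


def extract_feature(spec: FeatureSpec, timecourse: np.ndarray, time_ms: np.ndarray) -> float:
    """Extremal amplitude or latency within the closed window [t0, t1].

    Ties are broken to the earliest sample; the window must lie inside
    the sampled span.
    """
    timecourse = np.asarray(timecourse, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    # the epoch is half-open [t_first, t_last + dt): a window may end up to
    # one sample step past the last sample (e.g. 500-600 ms on a 0-596 ms grid)
    dt = time_ms[1] - time_ms[0] if time_ms.size > 1 else 0.0
    if spec.t0_ms < time_ms[0] - 1e-9 or spec.t1_ms > time_ms[-1] + dt + 1e-9:
        raise ValueError(
            f"window [{spec.t0_ms}, {spec.t1_ms}] ms outside sampled span "
            f"[{time_ms[0]}, {time_ms[-1]}] ms"
        )
    in_win = (time_ms >= spec.t0_ms - 1e-9) & (time_ms <= spec.t1_ms + 1e-9)
    idx = np.flatnonzero(in_win)
    seg = timecourse[idx]
    # np.argmin/argmax return the first occurrence: the earliest-sample tie rule
    j = int(np.argmin(seg) if spec.extremum == MIN else np.argmax(seg))
    if spec.returns == AMPLITUDE:
        return float(seg[j])
    return float(time_ms[idx[j]])


@dataclass
class FeatureMatrix:
    """Subjects x features values with group labels."""

    subject_ids: list
    group_labels: list
    feature_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValueError("values shape inconsistent with ids")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        feature_ids = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            subject_ids=df["subject_id"].tolist(),
            group_labels=df["group"].tolist(),
            feature_ids=feature_ids,
            values=df[feature_ids].to_numpy(dtype=float),
        )


def build_feature_matrix(
    dataset,
    model,
    specs,
    component_index: dict[str, int],
    condition_map: dict[str, str] | None = None,
    default_condition: str = "NOGO",
) -> FeatureMatrix:
    """Extract every spec for every subject.

    For each spec the component's back-projection is computed on the
    subject's ERP in the component's condition (``condition_map``,
    default NOGO — the novelty component maps to NOVEL), its time
    course at the spec's electrode taken, and the extremum extracted.
    """
    condition_map = condition_map or {}
    subject_ids = dataset.subject_ids
    groups = [dataset.group_of(s) for s in subject_ids]
    ch_index = {c: k for k, c in enumerate(model.channel_order)}

    values = np.empty((len(subject_ids), len(specs)))
    # cache one projected timecourse per (subject, component)
    for si, sid in enumerate(subject_ids):
        cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for fi, spec in enumerate(specs):
            if spec.component not in cache:
                cond = condition_map.get(spec.component, default_condition)
                try:
                    erp = dataset.get(sid, cond)
                except KeyError:
                    raise KeyError(
                        f"subject {sid!r} lacks condition {cond!r} required by component {spec.component!r}"
                    ) from None
                Pi = model.project(component_index[spec.component], erp.data)
                cache[spec.component] = (Pi, erp.time_ms)
            Pi, time_ms = cache[spec.component]
            values[si, fi] = extract_feature(spec, Pi[ch_index[spec.channel]], time_ms)
    return FeatureMatrix(
        subject_ids=subject_ids,
        group_labels=groups,
        feature_ids=[s.feature_id for s in specs],
        values=values,
    )
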