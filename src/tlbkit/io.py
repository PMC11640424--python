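"""Reading and writing thermogram cohorts in plain CSV formats.

A *thermogram* is one sample's excess heat capacity (Cp, arbitrary units)
versus temperature (°C) curve, as produced by differential scanning
calorimetry of a biological fluid.  A *cohort* bundles the thermograms of a
study together with binary class labels (``negative``/``positive``, e.g.
non-mucinous vs mucinous lesion) and a per-sample flag marking whether the
diagnosis is confirmed (histopathology) or only highly probable.

Two CSV dialects are supported:

* **long** — columns ``sample_id,temperature_C,cp``, one row per measured
  point, rows of a sample sorted by temperature;
* **wide** — column ``temperature_C`` followed by one column per sample
  (requires all samples to share a temperature grid).

Labels travel in a sidecar CSV with columns ``sample_id,label,confirmed``
(label ∈ {negative, positive}, confirmed ∈ {true, false}); any further
columns are carried as per-sample string metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

NEGATIVE = "negative"
POSITIVE = "positive"
LABELS = (NEGATIVE, POSITIVE)

_LONG_COLUMNS = ["sample_id", "temperature_C", "cp"]
_TEMP_COLUMN = "temperature_C"


@dataclass
class Thermogram:
    """One sample's (temperature, excess heat capacity) curve.

    Parameters
    ----------
    sample_id
        Opaque sample identifier (anonymization codes are not parsed).
    temperatures
        Strictly increasing temperatures in °C, length ≥ 2.
    cp
        Excess heat capacity at each temperature, arbitrary units.  Small
        negative values are legitimate before normalization (baseline
        correction may undershoot).
    meta
        Free-form string metadata (lesion subtype, diagnosis confidence...).
    """

    sample_id: str
    temperatures: np.ndarray
    cp: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, c = self.temperatures, self.cp
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise ValidationError(
                f"sample {self.sample_id!r}: temperatures and cp must be "
                f"1-D and of equal length (got {t.shape} vs {c.shape})"
            )
        if len(t) < 2:
            raise ValidationError(
                f"sample {self.sample_id!r}: need at least 2 points, got {len(t)}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValidationError(
                f"sample {self.sample_id!r}: non-finite temperature or cp value"
            )
        if not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: temperatures not strictly increasing"
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temperatures[0]), float(self.temperatures[-1])


@dataclass
class Cohort:
    """A set of thermograms with class labels and diagnosis-confidence flags.

    ``labels`` maps sample_id → ``"negative"``/``"positive"``; ``confirmed``
    maps sample_id → bool (confirmed vs high-probability diagnosis).  Both
    maps may cover a subset of samples, but never an unknown sample.
    """

    thermograms: list[Thermogram]
    labels: dict[str, str] = field(default_factory=dict)
    confirmed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [t.sample_id for t in self.thermograms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_ids: {dupes}")
        known = set(ids)
        for sid in self.labels:
            if sid not in known:
                raise ValidationError(f"label for unknown sample {sid!r}")
        for sid, lab in self.labels.items():
            if lab not in LABELS:
                raise ValidationError(
                    f"sample {sid!r}: label {lab!r} not in {LABELS}"
                )
        for sid in self.confirmed:
            if sid not in known:
                raise ValidationError(f"confirmed flag for unknown sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.thermograms]

    def __len__(self) -> int:
        return len(self.thermograms)

    def __getitem__(self, sample_id: str) -> Thermogram:
        for t in self.thermograms:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)

    def subset(self, sample_ids: list[str]) -> "Cohort":
        """Restrict to the given sample_ids (order preserved)."""
        keep = set(sample_ids)
        return Cohort(
            thermograms=[t for t in self.thermograms if t.sample_id in keep],
            labels={s: v for s, v in self.labels.items() if s in keep},
            confirmed={s: v for s, v in self.confirmed.items() if s in keep},
        )


def _labels_path_for(path: Path) -> Path:
    return path.with_suffix(".labels.csv")


def read_cohort(
    path: str | Path,
    layout: str = "long",
    labels_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path
        Thermogram CSV (long or wide dialect).
    layout
        ``"long"`` or ``"wide"``.
    labels_path
        Sidecar labels CSV; defaults to ``<path stem>.labels.csv`` next to
        ``path`` and is optional — a missing default sidecar yields an
        unlabeled cohort.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise FormatError(f"unknown layout {layout!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None

    if layout == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        thermograms = []
        for sid, grp in df.groupby("sample_id", sort=True):
            grp = grp.sort_values("temperature_C")
            t = grp["temperature_C"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"{path}: sample {sid!r} has duplicated or non-monotone "
                    "temperatures"
                )
            thermograms.append(
                Thermogram(str(sid), t, grp["cp"].to_numpy(float))
            )
    else:
        if _TEMP_COLUMN not in df.columns:
            raise FormatError(f"{path}: missing column {_TEMP_COLUMN!r}")
        sample_cols = [c for c in df.columns if c != _TEMP_COLUMN]
        if not sample_cols:
            raise FormatError(f"{path}: wide layout has no sample columns")
        df = df.sort_values(_TEMP_COLUMN)
        t = df[_TEMP_COLUMN].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path}: duplicated or non-monotone temperatures"
            )
        thermograms = [
            Thermogram(str(c), t.copy(), df[c].to_numpy(float))
            for c in sample_cols
        ]

    labels: dict[str, str] = {}
    confirmed: dict[str, bool] = {}
    meta_by_sample: dict[str, dict[str, str]] = {}
    lp = Path(labels_path) if labels_path is not None else _labels_path_for(path)
    if labels_path is not None or lp.exists():
        ldf = pd.read_csv(lp, dtype=str)
        missing = [c for c in ("sample_id", "label", "confirmed") if c not in ldf.columns]
        if missing:
            raise FormatError(f"{lp}: missing columns {missing}")
        meta_cols = [c for c in ldf.columns if c not in ("sample_id", "label", "confirmed")]
        for _, row in ldf.iterrows():
            sid = str(row["sample_id"])
            labels[sid] = str(row["label"])
            conf = str(row["confirmed"]).strip().lower()
            if conf not in ("true", "false"):
                raise FormatError(
                    f"{lp}: confirmed must be true/false, got {row['confirmed']!r}"
                )
            confirmed[sid] = conf == "true"
            meta = {
                c: str(row[c]) for c in meta_cols if pd.notna(row[c])
            }
            if meta:
                meta_by_sample[sid] = meta

    cohort = Cohort(thermograms, labels, confirmed)
    for t in cohort.thermograms:
        if t.sample_id in meta_by_sample:
            t.meta.update(meta_by_sample[t.sample_id])
    return cohort


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    layout: str = "long",
    labels_path: str | Path | None = None,
) -> None:
    """Write a cohort to CSV; inverse of :func:`read_cohort`.

    The labels/confirmed maps (plus any per-sample meta) go to the sidecar
    labels CSV, written whenever labels, flags or meta are present.
    """
    path = Path(path)
    if layout not in ("long", "wide"):
        raise FormatError(f"unknown layout {layout!r}")

    if layout == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": t.sample_id,
                    "temperature_C": t.temperatures,
                    "cp": t.cp,
                }
            )
            for t in cohort.thermograms
        ]
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=_LONG_COLUMNS)
        )
        out.to_csv(path, index=False)
    else:
        if cohort.thermograms:
            ref = cohort.thermograms[0].temperatures
            for t in cohort.thermograms[1:]:
                if len(t.temperatures) != len(ref) or not np.array_equal(
                    t.temperatures, ref
                ):
                    raise FormatError(
                        "wide layout requires a shared temperature grid; "
                        f"sample {t.sample_id!r} differs"
                    )
            data = {_TEMP_COLUMN: ref}
            data.update({t.sample_id: t.cp for t in cohort.thermograms})
            out = pd.DataFrame(data)
        else:
            out = pd.DataFrame(columns=[_TEMP_COLUMN])
        out.to_csv(path, index=False)

    has_meta = any(t.meta for t in cohort.thermograms)
    if cohort.labels or cohort.confirmed or has_meta:
        lp = Path(labels_path) if labels_path is not None else _labels_path_for(path)
        meta_keys: list[str] = []
        for t in cohort.thermograms:
            for k in t.meta:
                if k not in meta_keys:
                    meta_keys.append(k)
        rows = []
        for t in cohort.thermograms:
            sid = t.sample_id
            row = {
                "sample_id": sid,
                "label": cohort.labels.get(sid, ""),
                "confirmed": str(cohort.confirmed.get(sid, False)).lower(),
            }
            for k in meta_keys:
                row[k] = t.meta.get(k, "")
            rows.append(row)
        pd.DataFrame(rows, columns=["sample_id", "label", "confirmed", *meta_keys]).to_csv(
            lp, index=False
        )
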