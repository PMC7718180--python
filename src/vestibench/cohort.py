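"""Cohort container, clinical derived-feature rules, and delimited-text I/O.

A :class:`Cohort` wraps a patients × features table (float values, ``NaN``
marking missing entries), an optional stroke/neuritis label per patient, and an
acute-vestibular-syndrome (AVS) flag.  Missingness is exposed as an explicit
boolean mask so downstream consumers (notably matrix completion) can
distinguish an observed zero from an absent measurement.

The derived-feature rules implement the study's fixed clinical thresholds:

* video head-impulse test (vHIT) is pathological for a vestibulo-ocular reflex
  gain below 0.7 or in the presence of refixation saccades;
* spontaneous nystagmus (SPN) counts as suppressed when its slow-phase
  velocity drops by at least 40% under visual fixation;
* the subjective visual vertical (SVV) is abnormal outside 0 ± 2.5°.

All three rules propagate missing inputs as a missing (``None``) result using
three-valued logic rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .schema import FeatureSchema, SchemaError, default_schema

#: Canonical missing token in cohort files.
NA_TOKEN = "NA"

LABEL_STROKE = "stroke"
LABEL_NEURITIS = "neuritis"

VHIT_GAIN_CUTOFF = 0.7
SPN_SUPPRESSION_FRACTION = 0.40
SVV_NORMAL_RANGE_DEG = 2.5

_META_COLUMNS = ("patient_id", "label", "avs")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _or3(*vals: Optional[bool]) -> Optional[bool]:
    """Kleene three-valued OR: True dominates, else None if any input missing."""
    if any(v is True for v in vals):
        return True
    if any(v is None for v in vals):
        return None
    return False


def is_vhit_pathological(gain, refixation_saccades) -> Optional[bool]:
    """Rate a video head-impulse test as pathological.

    True iff the VOR gain is below 0.7 (the gain of exactly 0.7 is normal) or
    refixation saccades are present.  A missing input leaves the result
    undetermined unless the other input already decides it; both missing gives
    ``None``.
    """
    if not _is_missing(gain) and gain < 0:
        raise ValueError(f"vHIT gain must be >= 0, got {gain}")
    low_gain = None if _is_missing(gain) else bool(gain < VHIT_GAIN_CUTOFF)
    saccades = None if _is_missing(refixation_saccades) else bool(refixation_saccades)
    return _or3(low_gain, saccades)


def is_spn_suppressed(spv_without_fixation, spv_with_fixation) -> Optional[bool]:
    """Check fixation suppression of spontaneous nystagmus for one component.

    True iff the slow-phase velocity decreased by at least 40% on fixation.
    Undefined (``None``) when the without-fixation SPV is zero or either input
    is missing.
    """
    if _is_missing(spv_without_fixation) or _is_missing(spv_with_fixation):
        return None
    if spv_without_fixation < 0 or spv_with_fixation < 0:
        raise ValueError("slow-phase velocities must be >= 0")
    if spv_without_fixation == 0:
        return None
    drop = (spv_without_fixation - spv_with_fixation) / spv_without_fixation
    return bool(drop >= SPN_SUPPRESSION_FRACTION)


def is_spn_suppressed_any(
    spv_h_without, spv_h_with, spv_v_without=None, spv_v_with=None
) -> Optional[bool]:
    """Fixation suppression over horizontal and vertical SPN components.

    Positive if either component satisfies the ≥ 40% decrease criterion.
    """
    return _or3(
        is_spn_suppressed(spv_h_without, spv_h_with),
        is_spn_suppressed(spv_v_without, spv_v_with),
    )


def is_svv_abnormal(mean_deviation) -> Optional[bool]:
    """True iff the mean SVV deviation lies outside the normal range 0 ± 2.5°."""
    if _is_missing(mean_deviation):
        return None
    return bool(abs(mean_deviation) > SVV_NORMAL_RANGE_DEG)


@dataclass
class PatientRecord:
    """One patient's feature vector plus derived meta-items.

    A light accessor view onto a cohort row; ``features`` maps feature name to
    float or ``None`` (missing).
    """

    patient_id: str
    features: dict
    label: Optional[str]
    avs: Optional[bool]

    @property
    def age(self):
        return self.features.get("age")

    def _f(self, name):
        v = self.features.get(name)
        return None if _is_missing(v) else v

    def _fbool(self, name):
        v = self._f(name)
        return None if v is None else bool(v)

    def hints_components(self) -> dict:
        """The three HINTS items (each boolean or None).

        The head-impulse item is *normal HIT* — i.e. the negation of the
        aggregated vHIT-pathological rating.
        """
        path = self._fbool("vhit_pathological")
        return {
            "hit_normal": None if path is None else not path,
            "direction_changing_gen": self._fbool("gen_direction_changing"),
            "skew": self._fbool("skew_deviation"),
        }

    def abcd2_components(self) -> dict:
        """Raw inputs of the ABCD² score (value or None each)."""
        return {
            "age": self._f("age"),
            "sbp": self._f("sbp"),
            "dbp": self._f("dbp"),
            "unilateral_weakness": self._fbool("unilateral_weakness"),
            "speech_impairment_wo_weakness": self._fbool("speech_impairment_no_weakness"),
            "duration_minutes": self._f("symptom_duration_minutes"),
            "diabetes": self._fbool("diabetes"),
        }


class Cohort:
    """Ordered collection of patient records with a fixed feature schema.

    Parameters
    ----------
    values : pandas.DataFrame
        patients × features, float dtype, ``NaN`` for missing; index holds
        unique patient ids; columns must equal ``schema.names`` in order.
    labels : pandas.Series or None
        ``"stroke"``/``"neuritis"`` per patient; None when labels are hidden.
    avs : pandas.Series or None
        Boolean AVS-presentation flag per patient.
    """

    def __init__(self, values: pd.DataFrame, schema: FeatureSchema = None,
                 labels: pd.Series = None, avs: pd.Series = None):
        schema = schema or default_schema()
        if list(values.columns) != list(schema.names):
            raise SchemaError("cohort columns do not match schema feature order")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise SchemaError(f"duplicate patient_id {dup!r}")
        self.schema = schema
        self.values = values.astype(float)
        self.labels = None if labels is None else labels.reindex(values.index)
        self.avs = None if avs is None else avs.reindex(values.index)
        self._validate()

    def _validate(self):
        if self.labels is not None:
            bad = set(self.labels.dropna()) - {LABEL_STROKE, LABEL_NEURITIS}
            if bad:
                raise SchemaError(f"unknown labels: {sorted(bad)}")
        binary = self.schema.binary_names()
        vals = self.values[binary].to_numpy(float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise SchemaError(
                f"binary feature {binary[c]!r} of patient "
                f"{self.values.index[r]!r} is not in {{0,1}}"
            )

    # -- container protocol -------------------------------------------------
    def __len__(self):
        return len(self.values)

    @property
    def patient_ids(self):
        return list(self.values.index)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observation mask (True = value observed)."""
        return self.values.notna()

    def record(self, patient_id) -> PatientRecord:
        row = self.values.loc[patient_id]
        feats = {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
        label = None
        if self.labels is not None and not pd.isna(self.labels.loc[patient_id]):
            label = self.labels.loc[patient_id]
        avs = None
        if self.avs is not None and not pd.isna(self.avs.loc[patient_id]):
            avs = bool(self.avs.loc[patient_id])
        return PatientRecord(str(patient_id), feats, label, avs)

    def iter_records(self):
        for pid in self.values.index:
            yield self.record(pid)

    def subset(self, patient_ids) -> "Cohort":
        """Row subset (order follows ``patient_ids``)."""
        values = self.values.loc[patient_ids]
        labels = None if self.labels is None else self.labels.loc[patient_ids]
        avs = None if self.avs is None else self.avs.loc[patient_ids]
        return Cohort(values, self.schema, labels, avs)

    def y(self) -> np.ndarray:
        """Labels as 0/1 (stroke = 1). Raises if labels are hidden."""
        if self.labels is None:
            raise ValueError("cohort labels are hidden")
        if self.labels.isna().any():
            raise ValueError("cohort has unlabeled records")
        return (self.labels == LABEL_STROKE).to_numpy(int)

    def class_counts(self) -> dict:
        y = self.y()
        return {LABEL_STROKE: int(y.sum()), LABEL_NEURITIS: int(len(y) - y.sum())}


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV, one patient per row, ``NA`` for missing.

    Column order: ``patient_id, label, avs, <305 features>``; the label and
    AVS columns are omitted when the cohort does not carry them.
    """
    df = cohort.values.copy()
    if cohort.avs is not None:
        df.insert(0, "avs", cohort.avs.astype(int))
    if cohort.labels is not None:
        df.insert(0, "label", cohort.labels)
    df.index.name = "patient_id"
    # shortest round-trip repr so read(write(c)) is bit-exact
    df.to_csv(path, na_rep=NA_TOKEN, encoding="utf-8",
              float_format=lambda v: repr(float(v)))


def read_cohort(path, schema: FeatureSchema = None) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`.

    The read/write round trip preserves values, the missingness mask, and the
    record order exactly.  A file without a label column yields a cohort with
    hidden labels.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: missing patient_id column")
    unknown = [c for c in df.columns if c not in schema and c not in _META_COLUMNS]
    if unknown:
        raise SchemaError(f"{path}: unknown column {unknown[0]!r}")
    missing_cols = [c for c in schema.names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing feature column {missing_cols[0]!r}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate patient_id {dup!r}")
    df = df.set_index("patient_id")

    feat = df[list(schema.names)]
    probe = feat.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & feat.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"{path}: non-numeric cell at patient {feat.index[r]!r}, "
            f"column {feat.columns[c]!r}: {feat.iat[r, c]!r}"
        )
    # Python float() parsing is correctly rounded, so values survive the
    # write/read round trip bit-exactly (pd.to_numeric's parser is not)
    numeric = feat.astype(float)

    labels = df["label"] if "label" in df.columns else None
    avs = None
    if "avs" in df.columns:
        avs_num = pd.to_numeric(df["avs"], errors="coerce")
        avs = avs_num.astype(bool).where(avs_num.notna())
    return Cohort(numeric, schema, labels, avs)
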