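"""Feature schema for the vestibular cohort table.

The cohort carries 305 numeric/binary input features organised in six blocks
(history taking, cardiovascular risk factors, questionnaires, videooculography,
subjective visual vertical, posturography).  A small set of clinically named
features — including the ten most discriminative ones reported for this
classification problem — is defined explicitly; the remainder of each block is
padded with systematically named filler features so the schema always has
exactly 305 entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

N_FEATURES = 305

BLOCKS = ("history", "CVRF", "questionnaire", "VOG", "SVV", "posturography")

#: The ten features ranked most discriminative by the random-forest MDI
#: analysis, in rank order.
TABLE1_FEATURE_NAMES = (
    "vhit_pathological",
    "vhit_gain_right",
    "vor_fixation_suppression_gain",
    "smooth_pursuit_gain_down",
    "spn_present",
    "spn_spv_vertical",
    "gen_spv_right_horizontal",
    "spn_spv_horizontal",
    "gen_spv_left_horizontal",
    "spn_amplitude_std",
)

# (name, kind, unit, block); kind in {binary, continuous, ordinal}
_NAMED_FEATURES = [
    # --- history taking ---
    ("age", "continuous", "years", "history"),
    ("male", "binary", "flag", "history"),
    ("symptom_vertigo", "binary", "flag", "history"),
    ("symptom_dizziness", "binary", "flag", "history"),
    ("symptom_double_vision", "binary", "flag", "history"),
    ("symptom_onset_acute", "binary", "flag", "history"),
    ("symptom_duration_minutes", "continuous", "min", "history"),
    ("duration_10_60min", "binary", "flag", "history"),
    ("duration_ge_60min", "binary", "flag", "history"),
    ("symptom_intensity_vas", "continuous", "points", "history"),
    ("trigger_present", "binary", "flag", "history"),
    ("ear_symptoms", "binary", "flag", "history"),
    ("central_symptoms", "binary", "flag", "history"),
    ("unilateral_weakness", "binary", "flag", "history"),
    ("speech_impairment_no_weakness", "binary", "flag", "history"),
    # --- cardiovascular risk factors ---
    ("sbp", "continuous", "mmHg", "CVRF"),
    ("dbp", "continuous", "mmHg", "CVRF"),
    ("hypertension", "binary", "flag", "CVRF"),
    ("diabetes", "binary", "flag", "CVRF"),
    ("nicotine", "binary", "flag", "CVRF"),
    ("atrial_fibrillation", "binary", "flag", "CVRF"),
    ("family_history", "binary", "flag", "CVRF"),
    ("prior_stroke_mi", "binary", "flag", "CVRF"),
    # --- questionnaires ---
    ("eq5d_mobility", "ordinal", "points", "questionnaire"),
    ("eq5d_selfcare", "ordinal", "points", "questionnaire"),
    ("eq5d_activity", "ordinal", "points", "questionnaire"),
    ("eq5d_pain", "ordinal", "points", "questionnaire"),
    ("eq5d_anxiety", "ordinal", "points", "questionnaire"),
    ("eq_vas", "continuous", "points", "questionnaire"),
    ("dhi_total", "continuous", "points", "questionnaire"),
    ("mrs", "ordinal", "points", "questionnaire"),
    # --- videooculography ---
    ("vhit_pathological", "binary", "flag", "VOG"),
    ("vhit_gain_right", "continuous", "gain", "VOG"),
    ("vhit_gain_left", "continuous", "gain", "VOG"),
    ("vhit_refixation_saccades", "binary", "flag", "VOG"),
    ("vor_fixation_suppression_gain", "continuous", "gain", "VOG"),
    ("smooth_pursuit_gain_down", "continuous", "gain", "VOG"),
    ("spn_present", "binary", "flag", "VOG"),
    ("spn_spv_horizontal", "continuous", "deg/s", "VOG"),
    ("spn_spv_vertical", "continuous", "deg/s", "VOG"),
    ("spn_spv_horizontal_fixation", "continuous", "deg/s", "VOG"),
    ("spn_spv_vertical_fixation", "continuous", "deg/s", "VOG"),
    ("spn_suppressed_by_fixation", "binary", "flag", "VOG"),
    ("spn_amplitude_std", "continuous", "deg", "VOG"),
    ("gen_spv_right_horizontal", "continuous", "deg/s", "VOG"),
    ("gen_spv_left_horizontal", "continuous", "deg/s", "VOG"),
    ("gen_direction_changing", "binary", "flag", "VOG"),
    ("skew_deviation", "binary", "flag", "VOG"),
    # --- subjective visual vertical ---
    ("svv_mean_deviation", "continuous", "deg", "SVV"),
    ("svv_abnormal", "binary", "flag", "SVV"),
    # --- posturography ---
    ("sway_path_eo", "continuous", "mm", "posturography"),
    ("sway_path_ec", "continuous", "mm", "posturography"),
    ("sway_rms_ml", "continuous", "mm", "posturography"),
    ("sway_rms_ap", "continuous", "mm", "posturography"),
    ("sway_p2p_ml", "continuous", "mm", "posturography"),
    ("sway_p2p_ap", "continuous", "mm", "posturography"),
    ("sway_tandem_eo", "continuous", "mm", "posturography"),
    ("sway_tandem_ec", "continuous", "mm", "posturography"),
]

# How many filler features pad each block up to the 305 total.
_FILLER_PER_BLOCK = {
    "history": 40,
    "CVRF": 10,
    "questionnaire": 30,
    "VOG": 100,
    "SVV": 5,
    "posturography": 62,
}


class SchemaError(ValueError):
    """Raised when a cohort file or schema violates the feature contract."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered description of the cohort's feature columns.

    Attributes
    ----------
    names : tuple of str
        Feature identifiers, unique, in column order.
    kinds : tuple of str
        One of ``binary``, ``continuous``, ``ordinal`` per feature.
    units : tuple of str
        Measurement unit per feature (``flag`` for booleans).
    blocks : tuple of str
        Assessment block per feature.
    """

    names: tuple
    kinds: tuple
    units: tuple
    blocks: tuple
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (len(self.names) == len(self.kinds) == len(self.units) == len(self.blocks)):
            raise SchemaError("schema columns have mismatched lengths")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names are not unique")
        bad = set(self.kinds) - {"binary", "continuous", "ordinal"}
        if bad:
            raise SchemaError(f"unknown feature kinds: {sorted(bad)}")
        bad = set(self.blocks) - set(BLOCKS)
        if bad:
            raise SchemaError(f"unknown blocks: {sorted(bad)}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self):
        return len(self.names)

    def __contains__(self, name):
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SchemaError(f"unknown feature {name!r}") from None

    def kind(self, name: str) -> str:
        return self.kinds[self.index(name)]

    def binary_names(self) -> list:
        return [n for n, k in zip(self.names, self.kinds) if k == "binary"]

    def continuous_names(self) -> list:
        return [n for n, k in zip(self.names, self.kinds) if k != "binary"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "kind": self.kinds, "unit": self.units, "block": self.blocks}
        )


def default_schema() -> FeatureSchema:
    """Build the canonical 305-feature schema (version 1).

    Named clinical features come first within each block's declaration order;
    filler features are synthesised per block as ``<block>_q###``.
    """
    rows = list(_NAMED_FEATURES)
    for block in BLOCKS:
        for i in range(_FILLER_PER_BLOCK[block]):
            rows.append((f"{block.lower()}_q{i + 1:03d}", "continuous", "a.u.", block))
    if len(rows) != N_FEATURES:
        raise SchemaError(
            f"schema construction produced {len(rows)} features, expected {N_FEATURES}"
        )
    names, kinds, units, blocks = zip(*rows)
    return FeatureSchema(names, kinds, units, blocks)


def write_schema(schema: FeatureSchema, path) -> None:
    """Write a schema as a CSV of (name, kind, unit, block)."""
    schema.to_frame().to_csv(path, index=False)


def read_schema(path) -> FeatureSchema:
    """Read a schema CSV written by :func:`write_schema`."""
    df = pd.read_csv(path, dtype=str)
    required = {"name", "kind", "unit", "block"}
    if set(df.columns) != required:
        raise SchemaError(f"schema file {path} must have columns {sorted(required)}")
    return FeatureSchema(
        tuple(df["name"]), tuple(df["kind"]), tuple(df["unit"]), tuple(df["block"])
    )


def packaged_schema_path() -> Path:
    """Path of the schema text asset shipped with the package."""
    return Path(__file__).parent / "data" / "schema_v1.csv"
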