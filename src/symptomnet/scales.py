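"""Questionnaire scoring: Likert item tables -> construct (scale) scores.

The default instrument battery measures five constructs commonly studied
together in the perfectionism/procrastination literature:

* Positive / Negative Perfectionism (PANPS): 2 x 20 items, 5-point (1-5).
  Subscale scores are item sums, so each ranges 20-100.  A negative
  perfectionism sum of 69 or more is conventionally flagged as indicating
  negative-perfectionism tendencies.
* Cognitive Flexibility Inventory (CFI): 20 items, 7-point (1-7).
* Ruminative Response Scale (RRS): 22 items, 4-point (1-4).
* Tuckman Procrastination Scale: 16 items; the instrument's standard form
  is 4-point, which is the default here and configurable in the schema.

Construct scores are item sums (not means); no instrument in the default
battery declares reverse-keyed items, but the schema supports them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemSpec",
    "InstrumentSchema",
    "LikertResponseTable",
    "ScaleScoreTable",
    "CONSTRUCT_ORDER",
    "NEGATIVE_PERFECTIONISM_CUTOFF",
    "study_schema",
    "load_responses",
    "score_scales",
    "flag_negative_perfectionism",
]

#: Fixed column order of construct scores throughout the package.
CONSTRUCT_ORDER = (
    "Procrastination",
    "CognitiveFlexibility",
    "NegativePerfectionism",
    "PositivePerfectionism",
    "Rumination",
)

#: Sum score at or above which negative-perfectionism tendencies are flagged.
NEGATIVE_PERFECTIONISM_CUTOFF = 69


class SchemaError(ValueError):
    """The data do not match the instrument schema."""


class ResponseValidationError(ValueError):
    """A response value violates its item's category bounds."""


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    subscale: str
    minimum: int
    maximum: int
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.maximum <= self.minimum:
            raise SchemaError(f"item {self.item_id}: bad bounds [{self.minimum}, {self.maximum}]")


@dataclass
class InstrumentSchema:
    """Ordered item definitions grouped into subscales (constructs)."""

    items: list[ItemSpec]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate item ids in schema")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def subscales(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.subscale not in seen:
                seen.append(it.subscale)
        return seen

    def items_of(self, subscale: str) -> list[ItemSpec]:
        return [it for it in self.items if it.subscale == subscale]

    def score_bounds(self, subscale: str) -> tuple[int, int]:
        its = self.items_of(subscale)
        return (sum(i.minimum for i in its), sum(i.maximum for i in its))

    @classmethod
    def from_file(cls, path) -> "InstrumentSchema":
        """Read a YAML/JSON schema: a list of {item_id, subscale, min, max, reverse?}."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw, dict):
            raw = raw.get("items", raw)
        items = [
            ItemSpec(
                item_id=str(r["item_id"]),
                subscale=str(r["subscale"]),
                minimum=int(r["min"]),
                maximum=int(r["max"]),
                reverse=bool(r.get("reverse", False)),
            )
            for r in raw
        ]
        return cls(items)

    def to_file(self, path) -> None:
        rows = [
            {
                "item_id": it.item_id,
                "subscale": it.subscale,
                "min": it.minimum,
                "max": it.maximum,
                "reverse": it.reverse,
            }
            for it in self.items
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"items": rows}, fh, sort_keys=False)


def study_schema(tuckman_points: int = 4) -> InstrumentSchema:
    """The default 98-item battery (20+20+20+22+16 items, five constructs)."""
    items: list[ItemSpec] = []
    items += [ItemSpec(f"TPS{i:02d}", "Procrastination", 1, tuckman_points) for i in range(1, 17)]
    items += [ItemSpec(f"CFI{i:02d}", "CognitiveFlexibility", 1, 7) for i in range(1, 21)]
    items += [ItemSpec(f"PANPS_N{i:02d}", "NegativePerfectionism", 1, 5) for i in range(1, 21)]
    items += [ItemSpec(f"PANPS_P{i:02d}", "PositivePerfectionism", 1, 5) for i in range(1, 21)]
    items += [ItemSpec(f"RRS{i:02d}", "Rumination", 1, 4) for i in range(1, 23)]
    return InstrumentSchema(items)


@dataclass
class LikertResponseTable:
    """Participant x item ordinal response matrix (NaN marks missing)."""

    responses: np.ndarray  # float (n, m); NaN = missing
    item_ids: list[str]
    item_scale_map: dict[str, str]
    category_bounds: dict[str, tuple[int, int]]
    participant_ids: list[str]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (participants x items)")
        if self.responses.shape[0] == 0:
            raise ValueError("no participants")
        if self.responses.shape[1] != len(self.item_ids):
            raise ValueError("item_ids length does not match responses")
        for iid in self.item_ids:
            if iid not in self.item_scale_map:
                raise SchemaError(f"item {iid} not mapped to a subscale")

    @property
    def n_participants(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.responses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, index=self.participant_ids, columns=self.item_ids)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "participant_id"
        df.to_csv(path)


@dataclass
class ScaleScoreTable:
    """Participant x construct sum scores, fixed column order."""

    scores: pd.DataFrame  # participants x constructs
    score_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.scores, pd.DataFrame):
            self.scores = pd.DataFrame(np.asarray(self.scores, dtype=float))

    @property
    def construct_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def complete_cases(self) -> "ScaleScoreTable":
        return ScaleScoreTable(self.scores.dropna(axis=0, how="any"), dict(self.score_bounds))

    def to_csv(self, path) -> None:
        df = self.scores.copy()
        df.index.name = "participant_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ScaleScoreTable":
        df = pd.read_csv(path)
        if df.shape[0] == 0:
            raise ValueError("no participants")
        first = df.columns[0]
        if first.lower() in {"participant_id", "id", "participant"}:
            df = df.set_index(first)
        return cls(df.astype(float))


def load_responses(path, schema: InstrumentSchema) -> LikertResponseTable:
    """Read a participant x item CSV and validate it against *schema*.

    The CSV must carry a header row whose columns are the schema's item ids
    (an optional leading ``participant_id`` column is used as the row
    labels).  Rows with missing values are retained with NaN flags;
    out-of-range responses raise :class:`ResponseValidationError`.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError("no participants")
    first = df.columns[0]
    if first.lower() in {"participant_id", "id", "participant"}:
        df = df.set_index(first)
        df.index = df.index.astype(str)
    else:
        df.index = [str(i) for i in range(len(df))]
    unknown = [c for c in df.columns if c not in set(schema.item_ids)]
    if unknown:
        raise SchemaError(f"unknown items not in schema: {unknown[:5]}")
    missing_items = [c for c in schema.item_ids if c not in df.columns]
    if missing_items:
        raise SchemaError(f"schema items absent from CSV: {missing_items[:5]}")
    df = df[schema.item_ids].astype(float)

    bounds = {it.item_id: (it.minimum, it.maximum) for it in schema.items}
    arr = df.to_numpy()
    for j, iid in enumerate(schema.item_ids):
        lo, hi = bounds[iid]
        col = arr[:, j]
        bad = ~np.isnan(col) & ((col < lo) | (col > hi) | (col != np.round(col)))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ResponseValidationError(
                f"response {col[i]!r} out of range [{lo}, {hi}] "
                f"for item {iid}, participant {df.index[i]}"
            )
    return LikertResponseTable(
        responses=arr,
        item_ids=list(schema.item_ids),
        item_scale_map={it.item_id: it.subscale for it in schema.items},
        category_bounds=bounds,
        participant_ids=list(df.index),
    )


def _reverse_keyed(table: LikertResponseTable, schema: InstrumentSchema | None) -> np.ndarray:
    arr = table.responses.copy()
    if schema is None:
        return arr
    rev = {it.item_id for it in schema.items if it.reverse}
    for j, iid in enumerate(table.item_ids):
        if iid in rev:
            lo, hi = table.category_bounds[iid]
            arr[:, j] = (lo + hi) - arr[:, j]
    return arr


def score_scales(
    table: LikertResponseTable,
    missing_policy: str = "listwise",
    schema: InstrumentSchema | None = None,
    construct_order: tuple[str, ...] | None = None,
) -> ScaleScoreTable:
    """Sum item responses into construct scores.

    missing_policy
        ``"listwise"``: a participant missing any item of a construct gets
        NaN for that construct.  ``"impute"``: missing items are replaced by
        the participant's mean over the answered items of that construct
        (person-mean imputation); a construct with *all* items missing for
        some participant raises an error.
    """
    if missing_policy not in {"listwise", "impute"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    arr = _reverse_keyed(table, schema)
    subscales = []
    for iid in table.item_ids:
        s = table.item_scale_map[iid]
        if s not in subscales:
            subscales.append(s)
    if construct_order is None:
        construct_order = tuple(c for c in CONSTRUCT_ORDER if c in subscales) or tuple(subscales)
    missing_from_map = [c for c in construct_order if c not in subscales]
    if missing_from_map:
        raise SchemaError(f"constructs with no items present: {missing_from_map}")

    cols: dict[str, np.ndarray] = {}
    bounds: dict[str, tuple[int, int]] = {}
    for construct in construct_order:
        idx = [j for j, iid in enumerate(table.item_ids) if table.item_scale_map[iid] == construct]
        block = arr[:, idx]
        k = block.shape[1]
        nan_mask = np.isnan(block)
        if missing_policy == "listwise":
            score = block.sum(axis=1)
            score[nan_mask.any(axis=1)] = np.nan
        else:
            all_missing = nan_mask.all(axis=1)
            if all_missing.any():
                who = table.participant_ids[int(np.flatnonzero(all_missing)[0])]
                raise ValueError(
                    f"participant {who}: all {construct} items missing; cannot impute"
                )
            with np.errstate(invalid="ignore"):
                score = np.nanmean(block, axis=1) * k
        cols[construct] = score
        lo = sum(table.category_bounds[table.item_ids[j]][0] for j in idx)
        hi = sum(table.category_bounds[table.item_ids[j]][1] for j in idx)
        bounds[construct] = (lo, hi)

    df = pd.DataFrame(cols, index=table.participant_ids)[list(construct_order)]
    for c in construct_order:
        lo, hi = bounds[c]
        v = df[c].to_numpy()
        ok = np.isnan(v) | ((v >= lo) & (v <= hi))
        if not ok.all():
            raise ResponseValidationError(f"{c} score outside [{lo}, {hi}]")
    return ScaleScoreTable(df, bounds)


def flag_negative_perfectionism(score) -> bool | np.ndarray:
    """True where a negative-perfectionism sum score is at or above 69."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 20) | (arr > 100)):
        raise ValueError("negative perfectionism score outside [20, 100]")
    out = arr >= NEGATIVE_PERFECTIONISM_CUTOFF
    return bool(out) if np.isscalar(score) or arr.ndim == 0 else out
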