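"""ICD-10-CM-like code hierarchy: parsing, per-patient rollup, cross-site mapping.

Diagnosis codes live in a four-level hierarchy::

    chapter_block     G00-G99   (letter chapter)
    level2_category   G30-G32   (sub-chapter range)
    level3_category   G30       (three-character category)
    full_name         G30.9     (full code)

The hierarchy is supplied as a table (``hierarchy.tsv``: code, level, name,
parent) rather than hard-coded, so both the synthetic catalog and real
ICD-10-CM extracts work.  When a level-2 range or chapter block is absent
from the table, a syntactic fallback is derived from the code itself
(decade range for level 2, ``X00-X99`` for the block).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

LEVELS = ("chapter_block", "level2_category", "level3_category", "full_name")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9A-Z]{1,4})?$")
_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})-([A-Z])([0-9]{2})$")


class CodeParseError(ValueError):
    """Raised for a code that is not letter + two digits (+ .suffix)."""


@dataclass(frozen=True)
class HierarchyNode:
    code: str
    level: str
    name: str = ""
    parent: str | None = None


@dataclass
class Hierarchy:
    """Lookup structure over a hierarchy table."""

    names: dict[str, str] = field(default_factory=dict)
    level2_ranges: list[tuple[str, int, int, str]] = field(default_factory=list)
    block_ranges: list[tuple[str, int, int, str]] = field(default_factory=list)
    known_codes: set[str] = field(default_factory=set)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Hierarchy":
        h = cls()
        for row in frame.itertuples(index=False):
            code, level, name = str(row.code), str(row.level), str(row.name)
            h.names[code] = name
            h.known_codes.add(code)
            if level in ("level2_category", "chapter_block"):
                m = _RANGE_RE.match(code)
                if m and m.group(1) == m.group(3):
                    rng = (m.group(1), int(m.group(2)), int(m.group(4)), code)
                    if level == "level2_category":
                        h.level2_ranges.append(rng)
                    else:
                        h.block_ranges.append(rng)
        return h

    def name_of(self, code: str) -> str:
        return self.names.get(code, "")

    def _lookup_range(self, ranges, letter: str, num: int) -> str | None:
        for rl, lo, hi, code in ranges:
            if rl == letter and lo <= num <= hi:
                return code
        return None

    def level2_of(self, level3: str) -> str:
        letter, num = level3[0], int(level3[1:3])
        found = self._lookup_range(self.level2_ranges, letter, num)
        if found is not None:
            return found
        lo = (num // 10) * 10
        return f"{letter}{lo:02d}-{letter}{lo + 9:02d}"

    def block_of(self, level3: str) -> str:
        letter, num = level3[0], int(level3[1:3])
        found = self._lookup_range(self.block_ranges, letter, num)
        if found is not None:
            return found
        return f"{letter}00-{letter}99"


def parse_code(code: str, hierarchy: Hierarchy | None = None) -> list[HierarchyNode]:
    """Parse a diagnosis code into its chain of hierarchy nodes.

    Returns nodes ordered from chapter block down to the full code.  A
    three-character code yields no ``full_name`` node.

    Raises
    ------
    CodeParseError
        If the code is not syntactically valid.
    """
    code = str(code).strip().upper()
    if not _CODE_RE.match(code):
        raise CodeParseError(f"malformed diagnosis code: {code!r}")
    h = hierarchy or Hierarchy()
    level3 = code[:3]
    block = h.block_of(level3)
    level2 = h.level2_of(level3)
    chain = [
        HierarchyNode(block, "chapter_block", h.name_of(block)),
        HierarchyNode(level2, "level2_category", h.name_of(level2), block),
        HierarchyNode(level3, "level3_category", h.name_of(level3), level2),
    ]
    if len(code) > 3:
        chain.append(HierarchyNode(code, "full_name", h.name_of(code), level3))
    return chain


def _map_to_level(code: str, level: str, h: Hierarchy) -> str:
    """Map one raw code (or an already rolled-up code) to the requested level."""
    m = _RANGE_RE.match(code)
    if m:  # already a range code; idempotent at range levels
        if level in ("level2_category", "chapter_block"):
            letter, num = m.group(1), int(m.group(2))
            return code if level == "level2_category" else h.block_of(f"{letter}{num:02d}")
        raise CodeParseError(f"range code {code!r} cannot roll down to {level}")
    if not _CODE_RE.match(code):
        raise CodeParseError(f"malformed diagnosis code: {code!r}")
    if level == "full_name":
        return code
    level3 = code[:3]
    if level == "level3_category":
        return level3
    if level == "level2_category":
        return h.level2_of(level3)
    if level == "chapter_block":
        return h.block_of(level3)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def rollup(
    diagnoses: pd.DataFrame,
    level: str = "full_name",
    hierarchy: Hierarchy | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Roll a raw diagnosis event table up to per-patient deduplicated features.

    Each (patient, feature-at-level) pair is kept once with the earliest
    recorded date; distinct full codes sharing a parent collapse to one
    feature at coarser levels.

    Parameters
    ----------
    diagnoses
        Event table with columns ``patient_id``, ``code``, ``date``.
    level
        Target hierarchy level.
    strict
        If True, an unparseable code raises; otherwise it is logged and
        skipped (the sensible default for messy real-world extracts).

    Returns
    -------
    DataFrame with columns ``patient_id``, ``feature``, ``first_date``.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    h = hierarchy or Hierarchy()
    if diagnoses.empty:
        return pd.DataFrame(columns=["patient_id", "feature", "first_date"])
    codes = diagnoses["code"].astype(str).str.strip().str.upper()
    mapped = {}
    bad = set()
    for c in codes.unique():
        try:
            mapped[c] = _map_to_level(c, level, h)
        except CodeParseError:
            if strict:
                raise
            bad.add(c)
    if bad:
        log.warning("rollup: skipped %d unparseable codes (e.g. %s)", len(bad), sorted(bad)[:3])
    frame = pd.DataFrame(
        {
            "patient_id": diagnoses["patient_id"].to_numpy(),
            "feature": codes.map(mapped),
            "date": diagnoses["date"].to_numpy(),
        }
    ).dropna(subset=["feature"])
    out = (
        frame.groupby(["patient_id", "feature"], sort=True)["date"]
        .min()
        .reset_index()
        .rename(columns={"date": "first_date"})
    )
    return out


def feature_sets(rolled: pd.DataFrame, patient_ids=None) -> dict[str, set[str]]:
    """Turn a rollup frame into a dict patient -> set of feature codes.

    Patients listed in *patient_ids* but absent from the frame get empty sets.
    """
    sets: dict[str, set[str]] = {}
    if patient_ids is not None:
        sets = {str(p): set() for p in patient_ids}
    for pid, grp in rolled.groupby("patient_id"):
        key = str(pid)
        if patient_ids is not None and key not in sets:
            continue
        sets[key] = set(grp["feature"])
    return sets


def map_between_sites(
    features, code_map: dict[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Rename features through an inter-site code map.

    Returns (mapped: source -> target, unmapped: sources absent from the map).
    Collisions (two sources mapping to one target) are allowed — downstream
    presence/absence semantics merge them by logical OR — and logged.
    """
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for f in features:
        if f in code_map:
            mapped[f] = code_map[f]
        else:
            unmapped.append(f)
    targets = list(mapped.values())
    if len(set(targets)) < len(targets):
        log.warning("map_between_sites: %d target collisions merged by presence",
                    len(targets) - len(set(targets)))
    return mapped, unmapped
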