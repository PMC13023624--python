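"""Van Krevelen classification of assigned DOM molecular formulas.

Ultra-high-resolution mass spectrometry (FT-ICR-MS) of dissolved organic
matter yields elemental formulas CcHhOoNnSs with relative intensities.  Each
formula is placed on the Van Krevelen plane (H/C vs O/C atomic ratios) and
binned into one of seven compound classes common in natural DOM:

    lipids                  H/C 1.5-2.0,  O/C 0-0.3
    aliphatic / proteins    H/C 1.5-2.2,  O/C 0.3-0.67
    lignin / CRAM-like      H/C 0.7-1.5,  O/C 0.1-0.67
    carbohydrates           H/C 1.5-2.4,  O/C 0.67-1.2
    unsaturated hydrocarbons H/C 0.7-1.5, O/C 0-0.1
    aromatic structures     H/C 0.2-0.7,  O/C 0-0.67
    tannins                 H/C 0.6-1.5,  O/C 0.67-1

The published boxes share edges; to obtain a deterministic partition the
classifier applies them in the listed order with half-open [low, high)
intervals (the last class's upper bounds inclusive), first match wins, and
anything outside every box is kept as ``unassigned`` so shares still sum to
100.  Formulas are independently grouped by heteroatom content into
CHO / CHON / CHOS / CHONS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: (name, hc_low, hc_high, oc_low, oc_high) in classification precedence order
DEFAULT_CLASS_BOXES: tuple[tuple[str, float, float, float, float], ...] = (
    ("lipids", 1.5, 2.0, 0.0, 0.3),
    ("aliphatic_proteins", 1.5, 2.2, 0.3, 0.67),
    ("lignin_cram", 0.7, 1.5, 0.1, 0.67),
    ("carbohydrates", 1.5, 2.4, 0.67, 1.2),
    ("unsaturated_hc", 0.7, 1.5, 0.0, 0.1),
    ("aromatic", 0.2, 0.7, 0.0, 0.67),
    ("tannin", 0.6, 1.5, 0.67, 1.0),
)

CLASS_LABELS = tuple(name for name, *_ in DEFAULT_CLASS_BOXES) + ("unassigned",)
ELEMENT_GROUPS = ("CHO", "CHON", "CHOS", "CHONS")

_FORMULA_RE = re.compile(r"([CHONS])(\d*)")


@dataclass
class AssignedFormula:
    c: int
    h: int
    o: int = 0
    n: int = 0
    s: int = 0
    relative_intensity: float = 1.0
    sample_id: str = ""
    mz: float | None = None

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("formula must contain at least one carbon")
        if min(self.h, self.o, self.n, self.s) < 0:
            raise ValueError("atom counts must be >= 0")
        if not np.isfinite(self.relative_intensity) or self.relative_intensity < 0:
            raise ValueError("relative_intensity must be finite and >= 0")


@dataclass
class VKClassSummary:
    """Intensity (or count) shares over compound classes and element groups.

    Both partitions sum to 100 within numerical tolerance.
    """

    class_shares: dict[str, float]
    element_group_shares: dict[str, float]
    weighting: str
    n_formulas: int


def parse_formula(text: str) -> dict[str, int]:
    """Parse a C#H#O#N#S# formula string into atom counts."""
    counts = {"C": 0, "H": 0, "O": 0, "N": 0, "S": 0}
    matched_len = 0
    for m in _FORMULA_RE.finditer(text.strip()):
        counts[m.group(1)] = int(m.group(2) or 1)
        matched_len += len(m.group(0))
    if matched_len != len(text.strip()) or counts["C"] == 0:
        raise ValueError(f"unparseable formula {text!r}")
    return counts


def hc_oc(formula: AssignedFormula) -> tuple[float, float]:
    """H/C and O/C atomic ratios."""
    return formula.h / formula.c, formula.o / formula.c


def classify_vk(
    formula: AssignedFormula | tuple[float, float],
    boxes: Sequence[tuple[str, float, float, float, float]] = DEFAULT_CLASS_BOXES,
) -> str:
    """Compound-class label for a formula (or a raw (H/C, O/C) pair).

    First matching box in precedence order wins; intervals are half-open
    [low, high) except the final listed box, whose upper edges are inclusive.
    """
    if isinstance(formula, AssignedFormula):
        hc, oc = hc_oc(formula)
    else:
        hc, oc = formula
    last = len(boxes) - 1
    for i, (name, hc_lo, hc_hi, oc_lo, oc_hi) in enumerate(boxes):
        if i == last:
            if hc_lo <= hc <= hc_hi and oc_lo <= oc <= oc_hi:
                return name
        elif hc_lo <= hc < hc_hi and oc_lo <= oc < oc_hi:
            return name
    return "unassigned"


def element_group(formula: AssignedFormula) -> str:
    """CHO / CHON / CHOS / CHONS by heteroatom presence.

    Formulas without oxygen fall outside the standard DOM groups and are
    routed to an ``other`` bucket with a log notice.
    """
    if formula.o == 0:
        logger.info("formula C%dH%d lacks oxygen; grouped as 'other'", formula.c, formula.h)
        return "other"
    if formula.n > 0 and formula.s > 0:
        return "CHONS"
    if formula.n > 0:
        return "CHON"
    if formula.s > 0:
        return "CHOS"
    return "CHO"


def summarize(
    formulas: Iterable[AssignedFormula],
    weighting: str = "intensity",
    boxes: Sequence[tuple[str, float, float, float, float]] = DEFAULT_CLASS_BOXES,
) -> VKClassSummary:
    """Per-class and per-element-group shares (percent of total weight).

    ``weighting='intensity'`` uses relative intensities; ``'count'`` weights
    every formula equally.  Each partition sums to 100.
    """
    formulas = list(formulas)
    if not formulas:
        raise ValueError("empty formula list")
    if weighting == "intensity":
        w = np.array([f.relative_intensity for f in formulas], dtype=float)
    elif weighting == "count":
        w = np.ones(len(formulas))
    else:
        raise ValueError("weighting must be 'intensity' or 'count'")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")

    class_labels = tuple(name for name, *_ in boxes) + ("unassigned",)
    class_w = dict.fromkeys(class_labels, 0.0)
    group_w = dict.fromkeys(ELEMENT_GROUPS + ("other",), 0.0)
    for f, wi in zip(formulas, w):
        class_w[classify_vk(f, boxes)] += wi
        group_w[element_group(f)] += wi
    return VKClassSummary(
        class_shares={k: 100.0 * v / total for k, v in class_w.items()},
        element_group_shares={k: 100.0 * v / total for k, v in group_w.items()},
        weighting=weighting,
        n_formulas=len(formulas),
    )


def formulas_from_frame(df: pd.DataFrame, sample_id: str = "") -> list[AssignedFormula]:
    """Build formulas from a table with either a ``formula`` string column or
    per-element count columns c/h/o/n/s, plus ``relative_intensity``."""
    out = []
    for _, row in df.iterrows():
        if "formula" in df.columns and isinstance(row.get("formula"), str):
            counts = parse_formula(row["formula"])
            kw = {k.lower(): v for k, v in counts.items()}
        else:
            kw = {e: int(row.get(e, 0)) for e in ("c", "h", "o", "n", "s")}
        out.append(
            AssignedFormula(
                **kw,
                relative_intensity=float(row.get("relative_intensity", 1.0)),
                sample_id=str(row.get("sample_id", sample_id)),
                mz=float(row["mz"]) if "mz" in df.columns and pd.notna(row.get("mz")) else None,
            )
        )
    return out


def vk_scatter_table(formulas: Iterable[AssignedFormula]) -> pd.DataFrame:
    """Scatter coordinates for plotting: H/C, O/C, class and intensity per formula."""
    rows = []
    for f in formulas:
        hc, oc = hc_oc(f)
        rows.append(
            {"sample_id": f.sample_id, "hc": hc, "oc": oc,
             "vk_class": classify_vk(f), "element_group": element_group(f),
             "relative_intensity": f.relative_intensity}
        )
    return pd.DataFrame(rows)
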