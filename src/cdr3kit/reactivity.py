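"""Ordinal ELISA reactivity panels and sulfation-dependence calls.

Antibody reactivities against glycosaminoglycan antigens are recorded on a
five-level ordinal scale (absent, weak, moderate, strong, very strong,
printed as -, ±, +, ++, +++).  For panels that include chemically
desulfated heparins (N-desulfated/N-acetylated, 2-O-desulfated,
6-O-desulfated) the panel is interpreted with an auditable rule set:

* an antibody is a *binder* if its reference-heparin cell is at least
  moderate;
* the dependence of binding on a sulfate group is **essential** when the
  corresponding desulfated antigen gives no signal, **partial** when the
  signal is weak, and **non-essential** when it is moderate or stronger;
* an antibody whose binding requires every sulfate group tested targets a
  highly sulfated epitope (``high_sulfation``); one that tolerates the loss
  of each group targets a moderately sulfated epitope
  (``moderate_sulfation``); mixed or undeterminable profiles are
  ``pattern_specific``.

The 6-O call always carries a caveat: commercially 6-O-desulfated heparin
retains part of its 6-O sulfates (reported residual levels of 23% and about
30% exist for the preparation used here), so tolerance of "6-O desulfation"
is weaker evidence than for the other groups.

The two published panels (GAG cross-reactivity and modified-heparin) ship
as packaged CSV fixtures with per-row segmentation-confidence notes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import EmptyPanelError, PanelParseError

LEVEL_SYMBOLS: Mapping[str, int] = {"-": 0, "−": 0, "±": 1, "+": 2, "++": 3, "+++": 4}
LEVEL_NAMES: tuple[str, ...] = ("absent", "weak", "moderate", "strong", "very_strong")
SYMBOL_FOR_LEVEL: tuple[str, ...] = ("-", "±", "+", "++", "+++")

ROLES = frozenset(
    {
        "reference_heparin",
        "heparan_sulfate",
        "n_desulfated",
        "o2_desulfated",
        "o6_desulfated",
        "other_gag",
        "dna",
    }
)
_DESULFATED_ROLES = {
    "N": "n_desulfated",
    "2-O": "o2_desulfated",
    "6-O": "o6_desulfated",
}

#: Residual 6-O sulfation of the "6-O-desulfated" test antigen, as reported
#: in two places for the same preparation; recorded verbatim, not resolved.
RESIDUAL_6O_SULFATION_CAVEAT = (
    "6-O-desulfated heparin retains residual 6-O sulfation "
    "(reported as 23% and as about 30%)"
)

#: Dependence thresholds on the ordinal scale: level <= essential_max is
#: essential, <= partial_max partial, above that non-essential.  A binder
#: needs reference reactivity >= binder_min.
DEFAULT_THRESHOLDS: Mapping[str, int] = {
    "essential_max": 0,
    "partial_max": 1,
    "binder_min": 2,
}


@dataclass(frozen=True)
class ReactivityPanel:
    """Antigen x antibody ordinal level matrix with antigen role tags.

    ``levels`` is a DataFrame indexed by antigen name, columns antibody
    names, integer cells 0..4; ``roles`` maps antigen -> role tag; ``notes``
    keeps per-antigen free-text confidence annotations.
    """

    levels: pd.DataFrame
    roles: Mapping[str, str]
    notes: Mapping[str, str]

    @property
    def antibodies(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def antigens(self) -> list[str]:
        return list(self.levels.index)

    def reference_antigen(self) -> str:
        for antigen, role in self.roles.items():
            if role == "reference_heparin":
                return antigen
        raise EmptyPanelError("panel has no reference_heparin antigen")

    def antigens_with_role(self, role: str) -> list[str]:
        return [a for a, r in self.roles.items() if r == role]


def parse_panel(source: str | Path | io.TextIOBase) -> ReactivityPanel:
    """Read a reactivity panel CSV.

    Expected columns: ``antigen``, ``role``, one column per antibody, and
    an optional trailing ``note`` column.  Cells hold the ordinal symbols
    -, ±, +, ++, +++ (a bare Unicode minus is accepted).
    """
    df = pd.read_csv(source, dtype=str).fillna("")
    if df.empty or df.shape[1] < 3:
        raise EmptyPanelError("panel CSV has no antibody columns or no rows")
    for col in ("antigen", "role"):
        if col not in df.columns:
            raise PanelParseError(f"missing required column {col!r}")
    antibody_cols = [c for c in df.columns if c not in ("antigen", "role", "note")]
    if not antibody_cols:
        raise EmptyPanelError("panel CSV has no antibody columns")
    levels = {}
    roles = {}
    notes = {}
    for _, row in df.iterrows():
        antigen = row["antigen"]
        role = row["role"]
        if role not in ROLES:
            raise PanelParseError(f"unknown antigen role {role!r} for {antigen!r}")
        cells = []
        for ab in antibody_cols:
            symbol = row[ab].strip()
            if symbol not in LEVEL_SYMBOLS:
                raise PanelParseError(
                    f"unknown reactivity symbol {symbol!r} at "
                    f"antigen {antigen!r}, antibody {ab!r}"
                )
            cells.append(LEVEL_SYMBOLS[symbol])
        levels[antigen] = cells
        roles[antigen] = role
        notes[antigen] = row.get("note", "")
    frame = pd.DataFrame.from_dict(levels, orient="index", columns=antibody_cols)
    panel = ReactivityPanel(levels=frame, roles=roles, notes=notes)
    panel.reference_antigen()  # validate invariant
    return panel


def serialize_panel(panel: ReactivityPanel) -> str:
    """Panel back to CSV text (round-trips through :func:`parse_panel`)."""
    rows = ["antigen,role," + ",".join(panel.antibodies) + ",note"]
    for antigen in panel.antigens:
        symbols = [SYMBOL_FOR_LEVEL[v] for v in panel.levels.loc[antigen]]
        note = panel.notes.get(antigen, "")
        rows.append(
            f'{antigen},{panel.roles[antigen]},' + ",".join(symbols) + f',"{note}"'
        )
    return "\n".join(rows) + "\n"


def load_gag_panel() -> ReactivityPanel:
    """Packaged cross-reactivity panel (heparin, HS, other GAGs, DNA)."""
    path = resources.files("cdr3kit.data").joinpath("table5_gag_panel.csv")
    return parse_panel(io.StringIO(path.read_text()))


def load_modified_heparin_panel() -> ReactivityPanel:
    """Packaged modified-heparin (desulfation) panel."""
    path = resources.files("cdr3kit.data").joinpath(
        "table6_modified_heparin_panel.csv"
    )
    return parse_panel(io.StringIO(path.read_text()))


@dataclass(frozen=True)
class SulfationCall:
    """Sulfation-dependence interpretation for one antibody."""

    antibody: str
    dependence: Mapping[str, str]  # "N" / "2-O" / "6-O" -> dependence level
    overall_class: str
    caveats: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "antibody": self.antibody,
            "dependence": dict(self.dependence),
            "overall_class": self.overall_class,
            "caveats": list(self.caveats),
        }


def _dependence(level: int, thresholds: Mapping[str, int]) -> str:
    if level <= thresholds["essential_max"]:
        return "essential"
    if level <= thresholds["partial_max"]:
        return "partial"
    return "non-essential"


def call_sulfation_dependence(
    panel: ReactivityPanel, thresholds: Mapping[str, int] | None = None
) -> list[SulfationCall]:
    """Derive per-antibody sulfation-dependence calls from a panel.

    Missing desulfated antigens yield ``indeterminate`` dependence rather
    than an error.  Overall classes: ``non_binder`` (reference below
    moderate), ``high_sulfation`` (all three dependencies determined and
    essential), ``moderate_sulfation`` (all three determined, none
    essential), ``pattern_specific`` otherwise.
    """
    th = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    reference = panel.reference_antigen()
    calls = []
    for ab in panel.antibodies:
        caveats = [RESIDUAL_6O_SULFATION_CAVEAT]
        binder = panel.levels.loc[reference, ab] >= th["binder_min"]
        dependence: dict[str, str] = {}
        for group, role in _DESULFATED_ROLES.items():
            antigens = panel.antigens_with_role(role)
            if not binder or not antigens:
                dependence[group] = "indeterminate"
            else:
                level = int(max(panel.levels.loc[a, ab] for a in antigens))
                dependence[group] = _dependence(level, th)
        values = list(dependence.values())
        if not binder:
            overall = "non_binder"
        elif all(v == "essential" for v in values):
            overall = "high_sulfation"
        elif "indeterminate" not in values and "essential" not in values:
            overall = "moderate_sulfation"
        else:
            overall = "pattern_specific"
        calls.append(
            SulfationCall(
                antibody=ab,
                dependence=dependence,
                overall_class=overall,
                caveats=tuple(caveats),
            )
        )
    return calls


def specificity_summary(panel: ReactivityPanel) -> dict[str, list[str]]:
    """Per-antibody list of cross-reactive non-HS antigens.

    Cross-reactivity means at least moderate signal on an antigen tagged
    ``other_gag`` or ``dna`` (heparin and HS antigens are the intended
    targets and are excluded).
    """
    out: dict[str, list[str]] = {}
    cross = panel.antigens_with_role("other_gag") + panel.antigens_with_role("dna")
    for ab in panel.antibodies:
        out[ab] = [
            antigen
            for antigen in cross
            if panel.levels.loc[antigen, ab] >= DEFAULT_THRESHOLDS["binder_min"]
        ]
    return out


def calls_to_json(calls: list[SulfationCall], **kwargs) -> str:
    return json.dumps([c.to_dict() for c in calls], **kwargs)
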