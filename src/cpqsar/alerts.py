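"""Benigni–Bossa structural alerts for carcinogenicity.

A structural alert (SA) is a functional group or substructure associated,
mechanistically or statistically, with carcinogenic activity.  The packaged
rulebase carries the 33 Benigni–Bossa alerts as SMARTS patterns, each tagged
genotoxic (GA) or non-genotoxic (nGA).  On top of raw matching, molecules
are binned into the ten mechanistic groups used by the SA-prediction model:

    1 SA_7 | 2 SA_8 | 3 SA_13 | 4 SA_13+SA_27 | 5 SA_21 |
    6 SA_27 | 7 SA_27+SA_28 | 8 SA_28 | 9 other SA | 10 no alert

Combination groups 4 and 7 take precedence over their single-alert parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from rdkit import Chem

from .records import MoleculeRecord, StructureParseError

logger = logging.getLogger(__name__)

GENOTOXIC = "genotoxic"
NONGENOTOXIC = "nongenotoxic"

#: The six single-alert families with dedicated map groups.
GROUP_OF_SINGLE_ALERT = {
    "SA_7": 1, "SA_8": 2, "SA_13": 3, "SA_21": 5, "SA_27": 6, "SA_28": 8,
}
GROUP_OTHER_SA = 9
GROUP_NO_ALERT = 10
N_GROUPS = 10


class RulebaseError(ValueError):
    """Malformed rulebase file or pattern."""


@dataclass(frozen=True)
class StructuralAlert:
    alert_id: str
    name: str
    mechanism: str
    patterns: tuple[str, ...]
    example: str | None = None
    _compiled: tuple[Chem.Mol, ...] = field(default=(), repr=False, compare=False)

    def matches(self, mol: Chem.Mol) -> bool:
        return any(mol.HasSubstructMatch(q) for q in self._compiled)


@dataclass(frozen=True)
class Rulebase:
    alerts: tuple[StructuralAlert, ...]
    version: str

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self):
        return iter(self.alerts)

    def get(self, alert_id: str) -> StructuralAlert:
        for a in self.alerts:
            if a.alert_id == alert_id:
                return a
        raise KeyError(alert_id)

    @property
    def alert_ids(self) -> list[str]:
        return [a.alert_id for a in self.alerts]


@dataclass(frozen=True)
class AlertAnnotation:
    molecule_id: str
    alerts: frozenset[str]
    mechanism_summary: str  # GA | nGA | GA+nGA | NA
    rulebase_version: str


def load_rulebase(path: str | Path | None = None) -> Rulebase:
    """Load the packaged rulebase, or a user-supplied YAML in the same format."""
    if path is None:
        text = resources.files("cpqsar.data").joinpath("alerts_benigni_bossa.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        spec = yaml.safe_load(text)
        version = spec["version"]
        raw_alerts = spec["alerts"]
    except (yaml.YAMLError, TypeError, KeyError) as exc:
        raise RulebaseError(f"unreadable rulebase file: {exc}") from exc

    alerts = []
    seen: set[str] = set()
    for entry in raw_alerts:
        aid = entry["id"]
        if aid in seen:
            raise RulebaseError(f"duplicate alert id {aid}")
        seen.add(aid)
        mechanism = entry["mechanism"]
        if mechanism not in (GENOTOXIC, NONGENOTOXIC):
            raise RulebaseError(f"alert {aid}: unknown mechanism {mechanism!r}")
        compiled = []
        for p in entry["patterns"]:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise RulebaseError(f"alert {aid}: unparseable SMARTS {p!r}")
            compiled.append(q)
        alerts.append(
            StructuralAlert(
                alert_id=aid,
                name=entry["name"],
                mechanism=mechanism,
                patterns=tuple(entry["patterns"]),
                example=entry.get("example"),
                _compiled=tuple(compiled),
            )
        )
    rb = Rulebase(alerts=tuple(alerts), version=version)
    logger.info("loaded rulebase %s with %d alerts", version, len(rb))
    return rb


def _mechanism_summary(matched: set[str], rb: Rulebase) -> str:
    if not matched:
        return "NA"
    mechanisms = {rb.get(a).mechanism for a in matched}
    if mechanisms == {GENOTOXIC}:
        return "GA"
    if mechanisms == {NONGENOTOXIC}:
        return "nGA"
    return "GA+nGA"


def match_alerts(mol: MoleculeRecord | Chem.Mol | str, rb: Rulebase) -> AlertAnnotation:
    """All alerts whose any pattern matches the molecule."""
    if isinstance(mol, MoleculeRecord):
        mid, m = mol.id, mol.mol()
    elif isinstance(mol, str):
        mid = mol
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise StructureParseError(f"unparseable SMILES {mol!r}")
    else:
        mid, m = "", mol
    matched = {a.alert_id for a in rb if a.matches(m)}
    return AlertAnnotation(
        molecule_id=mid,
        alerts=frozenset(matched),
        mechanism_summary=_mechanism_summary(matched, rb),
        rulebase_version=rb.version,
    )


def group_label(annotation: AlertAnnotation | set[str] | frozenset[str]) -> int:
    """Map a matched-alert set to a mechanistic group 1..10.

    Precedence: the two combination groups first ({SA_13, SA_27} -> 4,
    {SA_27, SA_28} -> 7), then the single-alert groups when exactly one of
    the six family alerts matched, then 9 for any other non-empty set and 10
    for no alert.
    """
    matched = annotation.alerts if isinstance(annotation, AlertAnnotation) else frozenset(annotation)
    if not matched:
        return GROUP_NO_ALERT
    if {"SA_13", "SA_27"} <= matched:
        return 4
    if {"SA_27", "SA_28"} <= matched:
        return 7
    family = matched & GROUP_OF_SINGLE_ALERT.keys()
    if len(family) == 1:
        return GROUP_OF_SINGLE_ALERT[next(iter(family))]
    return GROUP_OTHER_SA


def annotate_dataset(
    mols: list[MoleculeRecord], rb: Rulebase
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-alert tally table plus the GA/nGA/GA+nGA/NA proportion summary.

    Returns a DataFrame with one row per alert (columns: matched, P, NP,
    unlabelled) and a dict of mechanism-summary proportions over molecules.
    The records' ``alerts`` fields are filled in place.
    """
    counts = {a.alert_id: {"matched": 0, "P": 0, "NP": 0, "unlabelled": 0} for a in rb}
    summary_counts = {"GA": 0, "nGA": 0, "GA+nGA": 0, "NA": 0}
    for rec in mols:
        ann = match_alerts(rec, rb)
        rec.alerts = set(ann.alerts)
        summary_counts[ann.mechanism_summary] += 1
        for aid in ann.alerts:
            row = counts[aid]
            row["matched"] += 1
            if rec.class_label == 2:
                row["P"] += 1
            elif rec.class_label == 1:
                row["NP"] += 1
            else:
                row["unlabelled"] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")
    table.index.name = "alert_id"
    n = len(mols)
    proportions = {k: (v / n if n else 0.0) for k, v in summary_counts.items()}
    return table, proportions


class StructuralAlertAnnotator:
    """Thin callable wrapper: annotate a batch of records with one rulebase."""

    def __init__(self, rulebase: Rulebase | None = None):
        self.rulebase = rulebase or load_rulebase()

    def __call__(self, mols: list[MoleculeRecord]) -> list[AlertAnnotation]:
        return [match_alerts(m, self.rulebase) for m in mols]
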