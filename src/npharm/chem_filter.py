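"""Drug-likeness rule systems and the oral-bioavailability candidate gate.

Five descriptor-threshold rule systems (Lipinski, Ghose, Veber, Egan,
Muegge) plus the Abbott bioavailability score are evaluated per compound.
A compound is retained as a candidate when it passes at least
``min_rules_passed`` rule systems (default 2) and its bioavailability
score is at least ``min_bas`` (default 0.30).

Threshold conventions follow the SwissADME implementations: Lipinski uses
MLOGP, Ghose and Egan use WLOGP, Muegge uses XLOGP3.  Range bounds are
inclusive except where the published rule is strict (Muegge requires
carbons > 4 and heteroatoms > 1).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

IONIZATION_CLASSES = frozenset({"anion", "cation", "neutral", "zwitterion"})

#: The five legal Abbott bioavailability score values (probability classes
#: for >10% oral bioavailability in rat).
BAS_VALUES = (0.11, 0.17, 0.55, 0.56, 0.85)

RULE_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")

NUMERIC_FIELDS = (
    "mw",
    "mlogp",
    "wlogp",
    "xlogp",
    "hbd",
    "hba",
    "tpsa",
    "rotatable_bonds",
    "molar_refractivity",
    "heavy_atoms",
    "rings",
    "carbons",
    "heteroatoms",
)


@dataclass(frozen=True)
class CompoundDescriptors:
    """Physicochemical descriptors of one compound.

    Units: ``mw`` in daltons, ``tpsa`` in Å²; the logP variants, counts and
    molar refractivity are unitless.  ``ionization_class`` is the dominant
    species at pH 6-7.
    """

    compound_id: str
    name: str
    mw: float
    mlogp: float
    wlogp: float
    xlogp: float
    hbd: int
    hba: int
    tpsa: float
    rotatable_bonds: int
    molar_refractivity: float
    heavy_atoms: int
    rings: int
    carbons: int
    heteroatoms: int
    ionization_class: str = "neutral"


def _check_finite(d: CompoundDescriptors) -> None:
    """Reject records with missing or non-finite descriptors."""
    for field in NUMERIC_FIELDS:
        value = getattr(d, field)
        if value is None or not math.isfinite(float(value)):
            raise ValueError(
                f"compound {d.compound_id!r}: descriptor {field!r} is "
                f"missing or non-finite ({value!r})"
            )


def evaluate_lipinski(d: CompoundDescriptors) -> tuple[int, bool]:
    """Rule-of-five check; up to one violation is tolerated.

    Violations counted: MW > 500, MLOGP > 4.15, H-bond donors > 5,
    H-bond acceptors > 10.

    Returns
    -------
    (violations, passed)
    """
    _check_finite(d)
    violations = sum(
        (d.mw > 500, d.mlogp > 4.15, d.hbd > 5, d.hba > 10)
    )
    return violations, violations <= 1


def evaluate_ghose(d: CompoundDescriptors) -> bool:
    """Ghose filter: 160 <= MW <= 480, -0.4 <= WLOGP <= 5.6,
    40 <= molar refractivity <= 130, 20 <= heavy atoms <= 70."""
    _check_finite(d)
    return (
        160 <= d.mw <= 480
        and -0.4 <= d.wlogp <= 5.6
        and 40 <= d.molar_refractivity <= 130
        and 20 <= d.heavy_atoms <= 70
    )


def evaluate_veber(d: CompoundDescriptors) -> bool:
    """Veber filter: rotatable bonds <= 10 and TPSA <= 140 Å²."""
    _check_finite(d)
    return d.rotatable_bonds <= 10 and d.tpsa <= 140


def evaluate_egan(d: CompoundDescriptors) -> bool:
    """Egan (BOILED-egg precursor) filter: WLOGP <= 5.88, TPSA <= 131.6 Å²."""
    _check_finite(d)
    return d.wlogp <= 5.88 and d.tpsa <= 131.6


def evaluate_muegge(d: CompoundDescriptors) -> bool:
    """Muegge (pharmacophore point) filter.

    200 <= MW <= 600, -2 <= XLOGP <= 5, TPSA <= 150, rings <= 7,
    carbons > 4, heteroatoms > 1, rotatable bonds <= 15, HBA <= 10,
    HBD <= 5.  The carbon and heteroatom bounds are strict.
    """
    _check_finite(d)
    return (
        200 <= d.mw <= 600
        and -2 <= d.xlogp <= 5
        and d.tpsa <= 150
        and d.rings <= 7
        and d.carbons > 4
        and d.heteroatoms > 1
        and d.rotatable_bonds <= 15
        and d.hba <= 10
        and d.hbd <= 5
    )


def abbott_bioavailability_score(
    d: CompoundDescriptors, unknown_ionization: str = "neutral"
) -> float:
    """Abbott bioavailability score (Martin 2005 decision tree).

    Anions are scored on TPSA alone (<=75 Å² -> 0.85; <=150 Å² -> 0.56;
    otherwise 0.11); all other ionization classes are scored on
    rule-of-five compliance (passed -> 0.55, failed -> 0.17).

    Parameters
    ----------
    unknown_ionization:
        Fallback class when ``ionization_class`` is not one of the four
        known classes; a warning is logged.
    """
    _check_finite(d)
    ion = d.ionization_class
    if ion not in IONIZATION_CLASSES:
        logger.warning(
            "compound %r: unknown ionization class %r, treating as %r",
            d.compound_id, ion, unknown_ionization,
        )
        ion = unknown_ionization
    if ion == "anion":
        if d.tpsa <= 75:
            return 0.85
        if d.tpsa <= 150:
            return 0.56
        return 0.11
    _, ro5_passed = evaluate_lipinski(d)
    return 0.55 if ro5_passed else 0.17


def evaluate_compound(
    d: CompoundDescriptors,
    min_rules_passed: int = 2,
    min_bas: float = 0.30,
) -> dict:
    """Evaluate all five rules plus the bioavailability gate for one compound."""
    violations, lipinski = evaluate_lipinski(d)
    flags = {
        "lipinski": lipinski,
        "ghose": evaluate_ghose(d),
        "veber": evaluate_veber(d),
        "egan": evaluate_egan(d),
        "muegge": evaluate_muegge(d),
    }
    bas = abbott_bioavailability_score(d)
    rules_passed = sum(flags.values())
    return {
        "compound_id": d.compound_id,
        "name": d.name,
        **flags,
        "lipinski_violations": violations,
        "bioavailability_score": bas,
        "rules_passed": rules_passed,
        "selected": rules_passed >= min_rules_passed and bas >= min_bas,
    }


def descriptors_from_frame(table: pd.DataFrame) -> list[CompoundDescriptors]:
    """Convert a descriptor table (one row per compound) to records."""
    names = [f.name for f in fields(CompoundDescriptors)]
    missing = set(names) - set(table.columns)
    if missing:
        raise ValueError(f"descriptor table lacks columns: {sorted(missing)}")
    return [
        CompoundDescriptors(**{k: row[k] for k in names})
        for row in table.to_dict("records")
    ]


def select_candidates(
    table: pd.DataFrame,
    min_rules_passed: int = 2,
    min_bas: float = 0.30,
) -> pd.DataFrame:
    """Apply the candidate gate to a descriptor table.

    Returns one verdict row per input row, in input order, with per-rule
    pass flags, the Lipinski violation count, the bioavailability score,
    the number of rules passed and the ``selected`` flag.

    Raises
    ------
    ValueError
        On duplicate compound ids (all duplicates listed) or on a missing
        or non-finite descriptor (the offending field is named).
    """
    ids = table["compound_id"]
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise ValueError(f"duplicate compound_id values: {dupes}")
    verdicts = [
        evaluate_compound(d, min_rules_passed, min_bas)
        for d in descriptors_from_frame(table)
    ]
    return pd.DataFrame(verdicts)


def funnel_summary(verdicts: pd.DataFrame) -> dict:
    """Counts entering and surviving the candidate gate."""
    return {
        "input_n": int(len(verdicts)),
        "selected_n": int(verdicts["selected"].sum()),
    }


def write_verdicts(verdicts: pd.DataFrame, path: str | Path) -> None:
    verdicts.to_csv(path, sep="\t", index=False)


def read_verdicts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_funnel(verdicts: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(funnel_summary(verdicts), sort_keys=True) + "\n")
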