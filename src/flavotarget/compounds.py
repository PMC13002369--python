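"""Local rule-based compound screening: formula parsing, mass computation,
SDF V2000 reading and drug-likeness filters.

Pharmacokinetics web screens cannot be recomputed offline; the default rule
set here is an explicit local proxy (Lipinski-style: MW <= 500, H-bond
donors <= 5, acceptors <= 10, logP <= 5) applied to whichever descriptors
the user supplies. Masses are computed from embedded isotope constants —
the screened flavonoid panel reports monoisotopic molecular weights, so the
monoisotopic path is the validated one and the average mass is reported
alongside.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


class CompoundError(ValueError):
    pass


class FormulaError(CompoundError):
    pass


#: lightest-isotope (= most abundant for CHNOPS) masses, IUPAC 2021, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.9720711744,
    "P": 30.9737619984,
    "F": 18.9984031627,
    "Cl": 34.968852682,
    "Br": 78.9183376,
    "I": 126.9044719,
}

#: standard atomic weights (conventional), Da
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998403,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.90447,
}

#: The screened flavonoid panel: (compound id, name, formula, reported
#: monoisotopic molecular weight to 2 dp).
FLAVONOID_PANEL: list[tuple[str, str, str, float]] = [
    ("MOL01", "Gardenin B", "C19H18O7", 358.11),
    ("MOL02", "Corymbosin", "C19H18O7", 358.11),
    ("MOL03", "5,4'-Dihydroxy-3,6,7,3'-tetramethoxyflavone", "C19H18O8", 374.10),
    ("MOL04", "Ayanin", "C18H16O7", 344.09),
    ("MOL05", "3,5-Dihydroxy-6,7,8,4'-tetramethoxyflavone", "C19H18O8", 374.10),
    ("MOL06", "Hymenoxin", "C19H18O8", 374.10),
    ("MOL07", "Cirsilineol", "C18H16O7", 344.09),
    ("MOL08", "Disporopsin", "C16H14O6", 302.08),
    ("MOL09", "Natsudaidain", "C21H22O9", 418.13),
    ("MOL10", "Retusin", "C19H18O7", 358.11),
    ("MOL11", "Kumatakenin", "C17H14O6", 314.08),
    ("MOL12", "Cupressuflavone", "C30H18O10", 538.09),
    ("MOL13", "Amentoflavone", "C30H18O10", 538.09),
    ("MOL14", "Apigenin", "C15H10O5", 270.05),
    ("MOL15", "Luteolin", "C15H10O6", 286.05),
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a plain molecular formula into element counts.

    Grammar: a sequence of element symbols each followed by an optional
    positive integer; no parentheses, charges or isotope labels. Raises
    :class:`FormulaError` naming the offending position.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element {element!r} in {text!r} at position {pos}"
            )
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count must be positive at position {pos} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill-order string (C, H, then alphabetical)."""
    items = dict(counts)
    order: list[str] = []
    for head in ("C", "H"):
        if items.get(head):
            order.append(head)
    order.extend(sorted(e for e in items if e not in ("C", "H") and items[e]))
    return "".join(f"{e}{items[e] if items[e] != 1 else ''}" for e in order)


def _mass(counts: Mapping[str, int], table: Mapping[str, float]) -> float:
    total = 0.0
    for element, n in counts.items():
        if n < 0:
            raise CompoundError(f"negative count for {element}")
        if element not in table:
            raise CompoundError(f"element {element!r} missing from mass table")
        total += n * table[element]
    return total


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Sum of lightest-isotope masses, Da."""
    return _mass(counts, MONOISOTOPIC_MASS)


def average_mass(counts: Mapping[str, int]) -> float:
    """Sum of standard atomic weights, Da."""
    return _mass(counts, AVERAGE_MASS)


def round2(value: float) -> float:
    """Round half-up to 2 decimals (matching printed molecular weights)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CompoundRecord:
    id: str
    name: str
    formula: str
    counts: dict[str, int]
    monoisotopic: float
    average: float
    descriptors: dict[str, float] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)
    lead: bool | None = None

    @classmethod
    def from_formula(
        cls, id: str, name: str, formula: str,
        descriptors: Mapping[str, float] | None = None,
    ) -> "CompoundRecord":
        counts = parse_formula(formula)
        return cls(
            id=id,
            name=name,
            formula=format_formula(counts),
            counts=counts,
            monoisotopic=monoisotopic_mass(counts),
            average=average_mass(counts),
            descriptors=dict(descriptors or {}),
        )


def flavonoid_records() -> list[CompoundRecord]:
    """The embedded screened flavonoid panel as compound records."""
    return [
        CompoundRecord.from_formula(cid, name, formula)
        for cid, name, formula, _ in FLAVONOID_PANEL
    ]


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------


def read_sdf(path: str | Path) -> list[CompoundRecord]:
    """Read a multi-record V2000 SDF; element counts from the atom block.

    Hydrogens are counted as written (no implicit-H inference). Records are
    delimited by ``$$$$``; the counts line is parsed by fixed columns.
    """
    text = Path(path).read_text()
    blocks = [b for b in text.split("$$$$") if b.strip()]
    records: list[CompoundRecord] = []
    for idx, block in enumerate(blocks):
        lines = block.lstrip("\n").splitlines()
        if len(lines) < 4:
            raise CompoundError(f"SDF record {idx}: truncated header")
        title = lines[0].strip()
        counts_line = lines[3]
        try:
            n_atoms = int(counts_line[0:3])
        except (ValueError, IndexError) as exc:
            raise CompoundError(
                f"SDF record {idx}: malformed counts line {counts_line!r}"
            ) from exc
        atom_lines = lines[4:4 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise CompoundError(f"SDF record {idx}: atom block shorter than counts line")
        counts: dict[str, int] = {}
        for a, line in enumerate(atom_lines):
            symbol = line[31:34].strip()
            if symbol not in MONOISOTOPIC_MASS:
                raise CompoundError(
                    f"SDF record {idx}, atom {a}: unknown element {symbol!r}"
                )
            counts[symbol] = counts.get(symbol, 0) + 1
        records.append(
            CompoundRecord(
                id=title or f"SDF{idx + 1:02d}",
                name=title or f"SDF{idx + 1:02d}",
                formula=format_formula(counts),
                counts=counts,
                monoisotopic=monoisotopic_mass(counts),
                average=average_mass(counts),
            )
        )
    return records


def write_sdf(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Minimal V2000 writer (zero coordinates, no bonds) for fixtures."""
    chunks = []
    for rec in records:
        n_atoms = sum(rec.counts.values())
        lines = [rec.id, "  flavotarget", "", f"{n_atoms:>3}  0  0  0  0  0  0  0  0  0999 V2000"]
        for element in sorted(rec.counts):
            for _ in range(rec.counts[element]):
                lines.append(
                    f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {element:<3}"
                    " 0  0  0  0  0  0  0  0  0  0  0  0"
                )
        lines.append("M  END")
        chunks.append("\n".join(lines))
    Path(path).write_text("\n$$$$\n".join(chunks) + "\n$$$$\n")


# ---------------------------------------------------------------------------
# Rule-based screening
# ---------------------------------------------------------------------------

#: default local drug-likeness proxy; each rule is (descriptor, limit).
#: "mw" is always computable (monoisotopic mass from the formula); note
#: that biflavonoids legitimately exceed the 500 Da cut — the rule set is
#: configurable precisely because the proxy is stricter than web screens.
DEFAULT_RULES: dict[str, tuple[str, float]] = {
    "mw<=500": ("mw", 500.0),
    "hbd<=5": ("hbd", 5.0),
    "hba<=10": ("hba", 10.0),
    "logp<=5": ("logp", 5.0),
}


def screen(
    records: Sequence[CompoundRecord],
    rules: Mapping[str, tuple[str, float]] | None = None,
) -> list[CompoundRecord]:
    """Apply drug-likeness rules; return the lead list.

    A rule is evaluated only when its input descriptor is present (``mw``
    always is); missing-descriptor rules are skipped with a warning. A
    compound is a lead when it passes every evaluated rule.
    """
    if not records:
        raise CompoundError("no compound records to screen")
    if rules is None:
        rules = DEFAULT_RULES
    import warnings

    leads: list[CompoundRecord] = []
    for rec in records:
        rec.verdicts = {}
        for rule_name, (descriptor, limit) in rules.items():
            if descriptor == "mw":
                value = rec.monoisotopic
            elif descriptor in rec.descriptors:
                value = rec.descriptors[descriptor]
            else:
                warnings.warn(
                    f"{rec.id}: descriptor {descriptor!r} absent; "
                    f"rule {rule_name!r} skipped",
                    stacklevel=2,
                )
                continue
            rec.verdicts[rule_name] = bool(value <= limit)
        rec.lead = all(rec.verdicts.values())
        if rec.lead:
            leads.append(rec)
    return leads


def read_descriptor_csv(path: str | Path) -> list[CompoundRecord]:
    """Compound descriptor CSV: id, name, formula, then optional numeric
    descriptor columns (hbd, hba, logp, tpsa, rotb)."""
    table = pd.read_csv(path)
    needed = {"id", "name", "formula"}
    if not needed <= set(table.columns):
        raise CompoundError(f"{path}: descriptor CSV needs columns {sorted(needed)}")
    extras = [c for c in table.columns if c not in needed]
    records = []
    for _, row in table.iterrows():
        desc = {
            c: float(row[c]) for c in extras if pd.notna(row[c])
        }
        records.append(
            CompoundRecord.from_formula(str(row["id"]), str(row["name"]),
                                        str(row["formula"]), desc)
        )
    return records


def screening_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "formula": [r.formula for r in records],
            "monoisotopic_mass": [round2(r.monoisotopic) for r in records],
            "average_mass": [round2(r.average) for r in records],
            "lead": [r.lead for r in records],
            "verdicts": [
                ";".join(f"{k}={'pass' if v else 'fail'}" for k, v in r.verdicts.items())
                for r in records
            ],
        }
    )
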