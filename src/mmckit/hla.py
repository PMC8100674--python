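"""HLA inheritance calculus for maternal-microchimerism studies.

Given mother/child genotypes at HLA-A, -B and -DRB1, this module derives, per
locus:

* the **inherited maternal allele** — the maternal allele the child carries;
* the **NIMA** (non-inherited maternal antigen) — the other maternal allele,
  which is the qPCR target used to detect maternal cells in the child;
* the **IPA** — the child's paternally inherited allele, foreign to the
  mother;
* **compatibility from the child's perspective** — whether every maternal
  allele group at the locus is present in the child, i.e. whether the child's
  immune system sees maternal cells as self at that locus.

All calculus is at first-field ("two-digit" allele group) resolution, which is
the resolution of the detection panel; higher-resolution typing strings are
truncated with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import MissingColumnError, NoSharedAlleleError

LOCI = ("A", "B", "DRB1")

#: Allele groups the default qPCR detection panel can target.  DRB1*15 and
#: DRB1*16 are covered by one combined probe, named "DRB1*15/16", that cannot
#: discriminate between them.
DEFAULT_PANEL_TARGETS = frozenset(
    {
        "DRB1*01",
        "DRB1*15/16",
        "DRB1*03",
        "DRB1*04",
        "DRB1*07",
        "DRB1*08",
        "DRB1*10",
        "DRB1*11",
        "DRB1*12",
        "DRB1*13",
        "DRB1*14",
        "A*01",
        "A*02",
        "A*11",
    }
)


@dataclass(frozen=True, order=True)
class HLAAllele:
    """An HLA allele group at first-field resolution, e.g. ``A*02``."""

    locus: str
    group: str  # two-digit first field, zero padded, e.g. "02"

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unsupported locus {self.locus!r}; expected one of {LOCI}")

    @property
    def name(self) -> str:
        return f"{self.locus}*{self.group}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name

    @classmethod
    def parse(cls, text: str, locus: Optional[str] = None) -> "HLAAllele":
        """Parse ``"A*02"``, ``"A*02:01"`` or bare ``"02"`` (locus given).

        Second-field and higher resolution is truncated to the allele group
        with a warning, since the detection panel only resolves groups.
        """
        s = str(text).strip()
        if "*" in s:
            loc, _, rest = s.partition("*")
            loc = loc.strip().upper()
            if locus is not None and loc != locus:
                raise ValueError(f"allele {text!r} does not match locus {locus}")
            locus = loc
        else:
            rest = s
            if locus is None:
                raise ValueError(f"bare allele group {text!r} needs an explicit locus")
        if ":" in rest:
            warnings.warn(
                f"allele {text!r} truncated to first-field resolution",
                stacklevel=2,
            )
            rest = rest.split(":", 1)[0]
        group = rest.strip().zfill(2)
        if not group.isdigit():
            raise ValueError(f"cannot parse allele group from {text!r}")
        return cls(locus=locus, group=group)


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pairs per typed locus; untyped loci are absent."""

    alleles: Mapping[str, tuple[HLAAllele, HLAAllele]]

    def __post_init__(self) -> None:
        # store sorted so that equality/compat calls ignore input ordering
        canon = {}
        for locus, pair in self.alleles.items():
            if locus not in LOCI:
                raise ValueError(f"unsupported locus {locus!r}")
            if len(pair) != 2:
                raise ValueError(f"locus {locus} needs exactly two alleles")
            canon[locus] = tuple(sorted(pair))
        object.__setattr__(self, "alleles", canon)

    @classmethod
    def from_strings(cls, **per_locus: Optional[Sequence[str]]) -> "Genotype":
        """Build from strings, e.g. ``Genotype.from_strings(A=("A*01", "02"))``."""
        alleles = {}
        for locus, pair in per_locus.items():
            if pair is None:
                continue
            alleles[locus] = tuple(HLAAllele.parse(a, locus) for a in pair)
        return cls(alleles)

    def typed(self, locus: str) -> bool:
        return locus in self.alleles

    def pair(self, locus: str) -> tuple[HLAAllele, HLAAllele]:
        return self.alleles[locus]

    def groups(self, locus: str) -> frozenset[str]:
        return frozenset(a.name for a in self.alleles[locus])

    def homozygous(self, locus: str) -> bool:
        a, b = self.alleles[locus]
        return a == b


class AssayPanel:
    """Set of allele groups the qPCR panel can target.

    Alleles covered by a combined probe (DRB1*15 and *16 by default) map to a
    single target; the membership test treats them as one.
    """

    def __init__(
        self,
        targets: Iterable[str] = DEFAULT_PANEL_TARGETS,
        combined: Mapping[str, str] | None = None,
    ):
        self.targets = frozenset(targets)
        # allele name -> panel target name
        if combined is None:
            combined = {"DRB1*15": "DRB1*15/16", "DRB1*16": "DRB1*15/16"}
        self._combined = dict(combined)

    def target_for(self, allele: HLAAllele) -> str:
        """Panel target name an allele would be detected by (covered or not)."""
        return self._combined.get(allele.name, allele.name)

    def covers(self, allele: HLAAllele) -> bool:
        return self.target_for(allele) in self.targets


@dataclass(frozen=True)
class InheritanceResult:
    """Per-locus decomposition of the child's genotype."""

    inherited: HLAAllele
    nima: HLAAllele
    ipa: HLAAllele
    ambiguous: bool = False  # mother het {X,Y} and child {X,Y}: assignment arbitrary


@dataclass(frozen=True)
class InformativityResult:
    informative: bool
    target: Optional[str] = None
    reason: Optional[str] = None  # shared | off-panel | mother-homozygous


def derive_inheritance(mother: Genotype, child: Genotype, locus: str) -> InheritanceResult:
    """Split the child's genotype into inherited-maternal / NIMA / IPA.

    The inherited maternal allele is a maternal allele present in the child;
    the NIMA is the other maternal allele (same group when the mother is
    homozygous); the IPA is the child allele not assigned as inherited.

    When the mother is heterozygous {X, Y} and the child is exactly {X, Y},
    inheritance cannot be resolved: the lexicographically smaller maternal
    allele is assigned as inherited (deterministic tie-break) and the result
    is flagged ``ambiguous``.  Compatibility and informativity remain
    well-defined in that case.

    Raises
    ------
    NoSharedAlleleError
        If the child shares no allele group with the mother (genotyping
        inconsistency or non-maternity).
    """
    m1, m2 = mother.pair(locus)
    c1, c2 = child.pair(locus)
    mgroups = {m1, m2}
    shared = [c for c in (c1, c2) if c in mgroups]
    if not shared:
        raise NoSharedAlleleError(
            f"no shared allele group at {locus}: mother {m1}/{m2}, child {c1}/{c2}"
        )
    child_in_mother = {c1 in mgroups, c2 in mgroups}
    if child_in_mother == {True, False}:
        inherited = c1 if c1 in mgroups else c2
        ipa = c2 if c1 in mgroups else c1
        nima = m2 if inherited == m1 else m1
        return InheritanceResult(inherited, nima, ipa, ambiguous=False)
    # both child alleles assignable to the mother
    if c1 == c2:
        # homozygous child: inherited and IPA are the same group
        inherited = c1
        nima = m2 if inherited == m1 else m1
        return InheritanceResult(inherited, nima, ipa=c2, ambiguous=False)
    # mother het {X,Y}, child {X,Y}: arbitrary but deterministic assignment
    inherited, other = sorted((c1, c2))
    return InheritanceResult(inherited, nima=other, ipa=other, ambiguous=True)


def classify_compatibility(mother: Genotype, child: Genotype, locus: str) -> bool:
    """Compatibility from the child's perspective at one locus.

    True iff every maternal allele group is present in the child's genotype —
    equivalently, the NIMA group is carried by the child — so maternal cells
    present nothing foreign to the child at this locus.
    """
    return child.groups(locus) >= mother.groups(locus)


def is_informative_target(
    mother: Genotype,
    child: Genotype,
    locus: str,
    panel: AssayPanel | None = None,
) -> InformativityResult:
    """Whether the NIMA at a locus is a usable maternal-cell detection target.

    Informative iff the mother is heterozygous, the NIMA's panel target is not
    hit by any child allele (non-shared — a probe amplifying the child's own
    DNA is useless), and the NIMA is covered by the panel.  DRB1*15 and *16
    share one probe, so a NIMA of *15 counts as shared when the child carries
    *16, even though *15 and *16 remain distinct for compatibility calls.
    """
    if panel is None:
        panel = AssayPanel()
    res = derive_inheritance(mother, child, locus)
    if mother.homozygous(locus):
        return InformativityResult(False, reason="mother-homozygous")
    target = panel.target_for(res.nima)
    child_targets = {panel.target_for(a) for a in child.pair(locus)}
    if target in child_targets:
        return InformativityResult(False, reason="shared")
    if target not in panel.targets:
        return InformativityResult(False, reason="off-panel")
    return InformativityResult(True, target=target)


@dataclass
class MotherChildPair:
    """A mother/child genotype pair with its per-locus derived calculus.

    Derived fields are ``None`` for untyped loci; a locus where the pair
    shares no allele is recorded in ``invalid_loci`` instead of raising.
    """

    pair_id: str
    mother: Genotype
    child: Genotype
    inheritance: dict[str, Optional[InheritanceResult]] = field(default_factory=dict)
    compatibility: dict[str, Optional[bool]] = field(default_factory=dict)
    invalid_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus in LOCI:
            if not (self.mother.typed(locus) and self.child.typed(locus)):
                self.inheritance[locus] = None
                self.compatibility[locus] = None
                continue
            try:
                self.inheritance[locus] = derive_inheritance(self.mother, self.child, locus)
            except NoSharedAlleleError:
                self.inheritance[locus] = None
                self.compatibility[locus] = None
                self.invalid_loci.append(locus)
                continue
            self.compatibility[locus] = classify_compatibility(self.mother, self.child, locus)

    @property
    def valid(self) -> bool:
        """False if any typed locus contradicts maternity."""
        return not self.invalid_loci

    def compatibility_any(self, loci: Sequence[str] = ("A", "DRB1")) -> Optional[bool]:
        """True iff compatible from the child's perspective at >=1 given locus.

        Untyped/invalid loci are not consulted; returns None when none of the
        requested loci carries a call.
        """
        calls = [self.compatibility[l] for l in loci if self.compatibility.get(l) is not None]
        if not calls:
            return None
        return any(calls)

    def informative_targets(self, panel: AssayPanel | None = None) -> dict[str, InformativityResult]:
        """Per-locus informativity for every typed, valid locus."""
        if panel is None:
            panel = AssayPanel()
        out = {}
        for locus in LOCI:
            if self.inheritance.get(locus) is None:
                continue
            out[locus] = is_informative_target(self.mother, self.child, locus, panel)
        return out

    def best_target(self, panel: AssayPanel | None = None,
                    preference: Sequence[str] = ("DRB1", "A")) -> Optional[tuple[str, str]]:
        """First informative (locus, panel target), DRB1 preferred by default."""
        info = self.informative_targets(panel)
        for locus in preference:
            r = info.get(locus)
            if r is not None and r.informative:
                return locus, r.target
        return None


GENOTYPE_COLUMNS = ["pair_id", "role", "A_1", "A_2", "B_1", "B_2", "DRB1_1", "DRB1_2"]


def read_genotypes(path: str | Path) -> list[MotherChildPair]:
    """Read the two-rows-per-pair genotype CSV into MotherChildPair objects.

    Expected columns: pair_id, role (mother|child), A_1, A_2, B_1, B_2,
    DRB1_1, DRB1_2.  Allele cells may be "A*02" or bare "02"; empty cells
    leave the locus untyped (both cells must then be empty).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"genotype file lacks columns {missing}")

    def row_genotype(row: pd.Series) -> Genotype:
        per_locus = {}
        for locus in LOCI:
            a, b = row.get(f"{locus}_1"), row.get(f"{locus}_2")
            a = None if pd.isna(a) or str(a).strip() == "" else a
            b = None if pd.isna(b) or str(b).strip() == "" else b
            if (a is None) != (b is None):
                raise ValueError(f"pair {row['pair_id']}: half-typed locus {locus}")
            if a is not None:
                per_locus[locus] = (a, b)
        return Genotype.from_strings(**per_locus)

    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        roles = grp.set_index(grp["role"].str.lower())
        if not {"mother", "child"} <= set(roles.index):
            raise ValueError(f"pair {pair_id}: need one mother and one child row")
        pairs.append(
            MotherChildPair(
                pair_id=str(pair_id),
                mother=row_genotype(roles.loc["mother"]),
                child=row_genotype(roles.loc["child"]),
            )
        )
    return pairs


def pairs_to_frame(pairs: Sequence[MotherChildPair], panel: AssayPanel | None = None) -> pd.DataFrame:
    """Flatten derived pair calculus into an analysis table (one row per pair)."""
    if panel is None:
        panel = AssayPanel()
    rows = []
    for p in pairs:
        row: dict = {"pair_id": p.pair_id, "valid": p.valid}
        for locus in LOCI:
            inh = p.inheritance.get(locus)
            row[f"compat_{locus}"] = p.compatibility.get(locus)
            row[f"nima_{locus}"] = inh.nima.name if inh else None
            row[f"ambiguous_{locus}"] = inh.ambiguous if inh else None
        row["compat_A_or_DRB1"] = p.compatibility_any(("A", "DRB1"))
        best = p.best_target(panel)
        row["target_locus"] = best[0] if best else None
        row["target"] = best[1] if best else None
        rows.append(row)
    return pd.DataFrame(rows)
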