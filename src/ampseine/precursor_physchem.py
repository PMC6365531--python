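"""Convertase-site splitting and physicochemical profiling of precursors.

Amphibian AMP precursors carry an N-terminal prepro region that is removed
at a dibasic Lys-Arg (KR) propeptide-convertase site, releasing the
C-terminal mature peptide.  Cleavage occurs C-terminal to the Arg; by
default the split is placed after the LAST K-R occurrence, which is the
placement that reproduces the reference precursor/mature boundaries even
when an additional KR lies near the N-terminus.

The mature peptide is profiled by formal net charge at neutral pH
((K + R) - (D + E), His and termini excluded), average molecular mass, and
isoelectric point (Henderson-Hasselbalch bisection).  Two pKa sets are
bundled; the default ("dtaselect") is the set that reproduces the
reference characterization-table pI values, "bjellqvist" is the set used
by the ExPASy pI tools.  Cysteines are treated as free (reduced) thiols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import get_logger

log = get_logger("physchem")

#: Average (isotope-weighted) residue masses in Da; water is added once per
#: peptide for the free termini.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.02

#: pKa sets: side chains of the ionizable residues plus the free termini.
#: "nterm" may be a single value or a residue-specific table with a
#: "default" entry.
PKA_SETS: dict[str, dict] = {
    # Reproduces the reference table's printed pI values (+/- 0.05).
    "dtaselect": {
        "nterm": 8.0, "cterm": 3.1,
        "C": 8.5, "D": 4.4, "E": 4.4, "H": 6.5,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
    # The set behind the ExPASy pI tools (residue-specific terminal pKa).
    "bjellqvist": {
        "nterm": {"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36,
                  "T": 6.82, "V": 7.44, "E": 7.70, "default": 7.50},
        "cterm": {"D": 4.55, "E": 4.75, "default": 3.55},
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}
DEFAULT_PKA_SET = "dtaselect"

ACIDIC = "DECY"
BASIC = "KRH"


@dataclass
class PrecursorPeptide:
    """A precursor split at a K-R convertase site into prepro and mature."""

    id: str
    precursor: str
    kr_sites: list[int]
    cleavage_index: int
    prepro: str
    mature: str

    def __post_init__(self) -> None:
        if self.prepro + self.mature != self.precursor:
            raise ValueError(f"{self.id}: prepro + mature must reconstruct the precursor")
        if not self.prepro.endswith("KR"):
            raise ValueError(f"{self.id}: prepro must end with the KR convertase motif")
        if self.cleavage_index != len(self.prepro):
            raise ValueError(f"{self.id}: cleavage_index must equal len(prepro)")
        if not self.kr_sites:
            raise ValueError(f"{self.id}: an accepted candidate needs at least one KR site")


@dataclass(frozen=True)
class PhyschemProfile:
    """Net charge, average mass, pI and length of a mature peptide."""

    net_charge: int
    avg_mass: float
    pI: float
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("profile requires a non-empty peptide")
        if self.avg_mass <= 0:
            raise ValueError("mass must be positive")
        if not 0 < self.pI < 14:
            raise ValueError("pI must lie strictly inside [0, 14]")


def find_kr_sites(precursor: str) -> list[int]:
    """0-based index of every Arg immediately preceded by Lys, excluding an
    Arg at the final position (whose mature fragment would be empty)."""
    return [
        i for i in range(1, len(precursor) - 1)
        if precursor[i] == "R" and precursor[i - 1] == "K"
    ]


def split_precursor(precursor: str, rule: str = "last_kr", id: str = "peptide"):
    """Split a precursor at its K-R convertase site(s).

    ``rule="last_kr"`` returns a single :class:`PrecursorPeptide` cleaved
    after the last K-R; ``rule="all"`` returns one per site.
    """
    sites = find_kr_sites(precursor)
    if not sites:
        raise ValueError(f"{id}: no convertase site (K-R) in precursor")
    if rule not in ("last_kr", "all"):
        raise ValueError(f"unknown cleavage rule {rule!r}")

    def _make(site: int) -> PrecursorPeptide:
        cut = site + 1
        return PrecursorPeptide(
            id=id, precursor=precursor, kr_sites=sites, cleavage_index=cut,
            prepro=precursor[:cut], mature=precursor[cut:],
        )

    if rule == "last_kr":
        return _make(sites[-1])
    return [_make(s) for s in sites]


def net_charge(pep: str) -> int:
    """Formal net charge at neutral pH: (K + R) - (D + E); His and the
    termini are excluded."""
    return pep.count("K") + pep.count("R") - pep.count("D") - pep.count("E")


def average_mass(pep: str) -> float:
    """Average molecular mass in Da (residue masses plus one water)."""
    try:
        return sum(RESIDUE_MASS[c] for c in pep) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in peptide") from None


def _pka(pka: dict, key: str, pep: str) -> float:
    value = pka[key]
    if isinstance(value, dict):
        residue = pep[0] if key == "nterm" else pep[-1]
        return value.get(residue, value["default"])
    return value


def charge_at_pH(pep: str, pH: float, pka_set: str = DEFAULT_PKA_SET) -> float:
    """Henderson-Hasselbalch net charge of *pep* at *pH*.

    Positive contributions from the N-terminus, K, R and H; negative from
    the C-terminus, D, E, C and Y.  Strictly decreasing in pH.
    """
    if not 0 <= pH <= 14:
        raise ValueError("pH must lie in [0, 14]")
    pka = PKA_SETS[pka_set]
    charge = 1.0 / (1.0 + 10 ** (pH - _pka(pka, "nterm", pep))) if pep else 0.0
    for res in BASIC:
        n = pep.count(res)
        if res == "H" and "H" not in pka:
            continue
        if n:
            charge += n / (1.0 + 10 ** (pH - pka[res]))
    if pep:
        charge -= 1.0 / (1.0 + 10 ** (_pka(pka, "cterm", pep) - pH))
    for res in ACIDIC:
        n = pep.count(res)
        if n:
            charge -= n / (1.0 + 10 ** (pka[res] - pH))
    return charge


def isoelectric_point(pep: str, pka_set: str = DEFAULT_PKA_SET,
                      tol: float = 1e-4, max_iter: int = 100) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero, by
    bisection on [0, 14] to |charge| < *tol* (or *max_iter* halvings).

    If the charge never crosses zero inside the interval the boundary is
    returned with a warning.
    """
    lo, hi = 0.0, 14.0
    qlo = charge_at_pH(pep, lo, pka_set)
    qhi = charge_at_pH(pep, hi, pka_set)
    if qlo <= 0:
        log.warning("peptide charge never positive; pI reported as pH 0")
        return lo
    if qhi >= 0:
        log.warning("peptide charge never negative; pI reported as pH 14")
        return hi
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = charge_at_pH(pep, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def profile_peptide(p: PrecursorPeptide, pka_set: str = DEFAULT_PKA_SET) -> PhyschemProfile:
    """Characterize the mature part of a split precursor."""
    mature = p.mature
    return PhyschemProfile(
        net_charge=net_charge(mature),
        avg_mass=average_mass(mature),
        pI=isoelectric_point(mature, pka_set),
        length=len(mature),
    )
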