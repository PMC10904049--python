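"""Protein charge accounting and basic-hydrophobic (BH) motif scoring.

Net charge is computed residue-by-residue with Henderson-Hasselbalch
titration under the unfolded-chain assumption: every ionizable side chain
(and, when the analyzed region spans a true terminus, the alpha-amino /
alpha-carboxyl group) titrates independently with a fixed pKa.  A
phosphoserine is modeled as a phosphomonoester whose first proton is fully
ionized and whose second titrates with pKa2 (default 5.8), so it adds
``-1 - 1/(1 + 10^(pKa2 - pH))`` elementary charges: -1.96 at pH 7.2 and
-1.86 at pH 6.6.

The BH scan scores sliding windows for the combination of net basic excess
and hydrophobicity that marks unstructured membrane-binding segments:
``score = max(0, B) * H`` where B is the (K+R minus D+E) count fraction and
H the window mean of min-max normalized Kyte-Doolittle hydropathy.  This is
a stated surrogate for the web-based BH predictors used in the field, with
the conventional positive-call threshold of 0.6.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy (J Mol Biol 1982), the default scale for H.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

BASIC_GROUPS = ("N-terminus", "H", "K", "R")
ACIDIC_GROUPS = ("C-terminus", "D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaSet:
    """pKa table for the nine ionizable groups of an unfolded chain."""

    values: dict[str, float]
    name: str = "custom"

    REQUIRED = ("N-terminus", "C-terminus", "D", "E", "H", "C", "Y", "K", "R")

    def __post_init__(self) -> None:
        missing = [g for g in self.REQUIRED if g not in self.values]
        if missing:
            raise ValueError(f"PkaSet missing groups: {missing}")
        for g, pk in self.values.items():
            if not 0 < pk < 14:
                raise ValueError(f"pKa for {g} out of (0, 14): {pk}")

    def __getitem__(self, group: str) -> float:
        return self.values[group]


#: Default table (standard unfolded-chain values); injectable everywhere.
DEFAULT_PKAS = PkaSet(
    values={
        "N-terminus": 9.0, "C-terminus": 3.1,
        "D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3,
        "Y": 10.07, "K": 10.53, "R": 12.48,
    },
    name="default-unfolded",
)


@dataclass(frozen=True)
class SiteModification:
    """A phosphoserine or point substitution at a 1-based position."""

    position: int
    kind: str  # "phosphoserine" | "substitution"
    new_residue: str | None = None
    pka2: float = 5.8

    def __post_init__(self) -> None:
        if self.kind not in ("phosphoserine", "substitution"):
            raise ValueError(f"unknown modification kind: {self.kind}")
        if self.kind == "substitution":
            if self.new_residue not in STANDARD_AA:
                raise ValueError(f"invalid new_residue: {self.new_residue}")
        if not 0 < self.pka2 < 14:
            raise ValueError(f"pka2 out of (0, 14): {self.pka2}")


def parse_region(text: str) -> tuple[int, int]:
    """Parse user-facing inclusive '251-307' into internal half-open (251, 308)."""
    m = re.fullmatch(r"\s*(\d+)\s*[-–]\s*(\d+)\s*", text)
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected 'start-end'")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid region bounds: {text!r}")
    return lo, hi + 1


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter sequence with named regions and site modifications.

    Regions are half-open [start, end) over 1-based residue numbering.
    """

    id: str
    residues: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    modifications: tuple[SiteModification, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues in {self.id}: {sorted(bad)}")
        n = len(self.residues)
        for name, (lo, hi) in self.regions.items():
            if not (1 <= lo <= hi <= n + 1):
                raise ValueError(f"region {name} [{lo},{hi}) outside [1,{n}]")
        seen: set[int] = set()
        for mod in self.modifications:
            if not 1 <= mod.position <= n:
                raise ValueError(f"modification position {mod.position} outside sequence")
            if mod.position in seen:
                raise ValueError(f"duplicate modification at {mod.position}")
            seen.add(mod.position)
            if (mod.kind == "phosphoserine"
                    and self.residues[mod.position - 1] != "S"):
                raise ValueError(
                    f"phosphoserine at non-Ser position {mod.position}")
        object.__setattr__(self, "modifications", tuple(self.modifications))

    def __len__(self) -> int:
        return len(self.residues)

    def region_bounds(self, region: str | None) -> tuple[int, int]:
        if region is None:
            return 1, len(self.residues) + 1
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r} on {self.id}") from None

    def effective_residues(self) -> str:
        """Residue string with substitution modifications applied."""
        chars = list(self.residues)
        for mod in self.modifications:
            if mod.kind == "substitution":
                chars[mod.position - 1] = mod.new_residue
        return "".join(chars)


@dataclass(frozen=True)
class ChargeReport:
    """Net charge at one pH, decomposed per ionizable group."""

    pH: float
    net_charge: float
    per_group_contributions: dict[str, float]
    modification_delta: float
    pka_set_name: str


@dataclass(frozen=True)
class BhProfile:
    """Sliding-window BH scores; index i scores the window starting at residue i+1."""

    window_length: int
    scores: np.ndarray
    threshold: float = 0.6

    @property
    def centers(self) -> np.ndarray:
        """1-based center residue position of each window."""
        half = self.window_length // 2
        return np.arange(len(self.scores)) + 1 + half

    def above_threshold(self) -> np.ndarray:
        return self.centers[self.scores > self.threshold]


def _basic(pH: float, pka: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def _acidic(pH: float, pka: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def phosphoserine_charge(pH: float, pka2: float = 5.8) -> float:
    """Charge added by O-phosphorylation of a serine.

    First phosphate proton fully ionized (-1); second titrating with pKa2.
    """
    return -1.0 - 1.0 / (1.0 + 10.0 ** (pka2 - pH))


def net_charge(seq: ProteinSequence, pH: float,
               pkas: PkaSet = DEFAULT_PKAS,
               region: str | None = None) -> ChargeReport:
    """Henderson-Hasselbalch net charge of a sequence (or named region).

    Basic groups contribute ``+1/(1+10^(pH-pKa))``, acidic groups
    ``-1/(1+10^(pKa-pH))``; the alpha-amino / alpha-carboxyl termini are
    counted only when the region reaches the corresponding true terminus.
    Substitution modifications change the titrating residue; phosphoserines
    add the phosphate term.  Returns the decomposition per group.
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH out of (0, 14): {pH}")
    lo, hi = seq.region_bounds(region)

    def accumulate(residues: str, phospho_positions: dict[int, float]):
        contrib: dict[str, float] = {}
        if lo == 1:
            contrib["N-terminus"] = _basic(pH, pkas["N-terminus"])
        if hi == len(seq.residues) + 1:
            contrib["C-terminus"] = _acidic(pH, pkas["C-terminus"])
        for pos in range(lo, hi):
            aa = residues[pos - 1]
            if pos in phospho_positions:
                contrib["phospho"] = contrib.get("phospho", 0.0) + \
                    phosphoserine_charge(pH, phospho_positions[pos])
                continue
            if aa in ("K", "R", "H"):
                contrib[aa] = contrib.get(aa, 0.0) + _basic(pH, pkas[aa])
            elif aa in ("D", "E", "C", "Y"):
                contrib[aa] = contrib.get(aa, 0.0) + _acidic(pH, pkas[aa])
        return contrib

    phospho = {m.position: m.pka2 for m in seq.modifications
               if m.kind == "phosphoserine" and lo <= m.position < hi}
    with_mods = accumulate(seq.effective_residues(), phospho)
    without = accumulate(seq.residues, {})
    total = sum(with_mods.values())
    delta = total - sum(without.values())
    return ChargeReport(pH=pH, net_charge=total,
                        per_group_contributions=with_mods,
                        modification_delta=delta, pka_set_name=pkas.name)


def residue_excess(seq: ProteinSequence, region: str | None = None) -> int:
    """count(R) + count(K) - count(D) - count(E) over the region."""
    lo, hi = seq.region_bounds(region)
    sub = seq.effective_residues()[lo - 1:hi - 1]
    return sub.count("R") + sub.count("K") - sub.count("D") - sub.count("E")


def apply_variant(seq: ProteinSequence,
                  substitutions: list[tuple[int, str]],
                  new_id: str | None = None) -> ProteinSequence:
    """Return a new sequence with point substitutions applied; input unchanged."""
    chars = list(seq.residues)
    for pos, aa in substitutions:
        if not 1 <= pos <= len(chars):
            raise ValueError(f"substitution position {pos} out of range")
        if aa not in STANDARD_AA:
            raise ValueError(f"invalid residue {aa!r}")
        chars[pos - 1] = aa
    return replace(seq, id=new_id or seq.id, residues="".join(chars))


def bh_scan(seq: ProteinSequence, window_length: int = 19,
            hydrophobicity_scale: dict[str, float] | None = None,
            threshold: float = 0.6) -> BhProfile:
    """Sliding-window basic-hydrophobic score.

    Per window of length L: ``B = (n_K + n_R - n_D - n_E)/L`` and ``H`` the
    mean min-max normalized hydropathy; ``score = max(0, B) * H``.  Windows
    are emitted only where fully supported (profile is L-1 shorter than the
    sequence).
    """
    if window_length % 2 == 0 or window_length < 5:
        raise ValueError("window_length must be odd and >= 5")
    if window_length > len(seq):
        raise ValueError("window longer than sequence")
    scale = hydrophobicity_scale or KYTE_DOOLITTLE
    lo_h, hi_h = min(scale.values()), max(scale.values())
    span = hi_h - lo_h
    res = np.frombuffer(seq.effective_residues().encode(), dtype="S1")
    norm_h = np.array([(scale[chr(c[0])] - lo_h) / span for c in res])
    basic = np.isin(res, [b"K", b"R"]).astype(float)
    acidic = np.isin(res, [b"D", b"E"]).astype(float)
    kern = np.ones(window_length)
    b = (np.convolve(basic - acidic, kern, "valid")) / window_length
    h = np.convolve(norm_h, kern, "valid") / window_length
    scores = np.maximum(b, 0.0) * h
    return BhProfile(window_length=window_length, scores=scores,
                     threshold=threshold)


def read_fasta(path, regions: dict[str, tuple[int, int]] | None = None
               ) -> list[ProteinSequence]:
    """Load protein sequences from a FASTA file; record IDs kept verbatim."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper(),
                                   regions=dict(regions or {})))
    return out
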