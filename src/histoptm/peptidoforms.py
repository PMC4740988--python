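"""Combinatorial histone peptidoforms and their masses.

A *peptidoform* is one combinatorial modification state of a tryptic histone
peptide — e.g. GKGGKGLGKGGAKR (H4 aa 4-17) with K5ac and K16ac, all other
lysines unmodified.  Histones are chemically propionylated before and after
trypsin digestion, so the neutral mass of a form includes a propionyl group
on the peptide N-terminus and on every lysine whose side chain can still
react (unmodified or monomethylated); acetylated, dimethylated and
trimethylated lysines are blocked and receive no propionyl.

Peptidoforms are keyed "histone:start-end:modstring" for interchange tables,
where modstring is a dot-joined list like "K5ac.K16ac" listing only modified
residues ("unmod" when nothing is modified).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .masses import KNOWN_CODES, MOD_MASS, PROTON_MASS, RESIDUE_MASS

__all__ = [
    "Peptidoform",
    "PeptideDefinition",
    "build_peptidoform_library",
    "compute_mz",
    "compute_neutral_mass",
    "parse_form_key",
    "mark_label",
    "default_histone_library",
]

# Lysine codes whose side chain remains reactive toward propionic anhydride.
_PROPIONYLATABLE = frozenset({"un", "me1"})

_KEY_RE = re.compile(r"^(?P<histone>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<mods>.+)$")
_MOD_RE = re.compile(r"^K(?P<res>\d+)(?P<code>me1|me2|me3|ac)$")


@dataclass(frozen=True)
class Peptidoform:
    """One combinatorial modification state of a histone peptide.

    Parameters
    ----------
    histone : str
        Histone identifier ("H3" or "H4").
    sequence : str
        Peptide backbone sequence, one-letter codes.
    start_res, end_res : int
        1-based inclusive residue numbers in the protein.
    mods : dict[int, str]
        Residue number -> modification code (``un``/``me1``/``me2``/``me3``/
        ``ac``).  Propionylation is implicit via the derivatization rules.
    """

    histone: str
    sequence: str
    start_res: int
    end_res: int
    mods: tuple[tuple[int, str], ...]
    neutral_mass: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.end_res - self.start_res + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start_res}-{self.end_res} does not match "
                f"sequence length {len(self.sequence)}"
            )
        for res, code in self.mods:
            if not (self.start_res <= res <= self.end_res):
                raise ValueError(f"modified residue {res} outside span "
                                 f"{self.start_res}-{self.end_res}")
            if code not in KNOWN_CODES:
                raise ValueError(f"unknown modification code {code!r}")
        if len({r for r, _ in self.mods}) != len(self.mods):
            raise ValueError("a residue may carry at most one modification")
        if self.neutral_mass == 0.0:
            object.__setattr__(self, "neutral_mass", compute_neutral_mass(self))

    @property
    def mod_dict(self) -> dict[int, str]:
        return dict(self.mods)

    @property
    def family(self) -> str:
        """Peptide family key: all forms sharing backbone and span."""
        return f"{self.histone}:{self.start_res}-{self.end_res}"

    @property
    def key(self) -> str:
        parts = [f"K{r}{c}" for r, c in sorted(self.mods) if c != "un"]
        modstr = ".".join(parts) if parts else "unmod"
        return f"{self.family}:{modstr}"

    @property
    def marks(self) -> tuple[str, ...]:
        """Single-mark labels carried by this form, e.g. ('H3K9me2', 'H3K14ac')."""
        return tuple(
            mark_label(self.histone, r, c) for r, c in sorted(self.mods) if c != "un"
        )

    def acetyl_count(self) -> int:
        return sum(1 for _, c in self.mods if c == "ac")


def mark_label(histone: str, residue: int, code: str) -> str:
    """Interchange label for a single PTM, e.g. ``H3K27me3``."""
    return f"{histone}K{residue}{code}"


def compute_neutral_mass(p: Peptidoform) -> float:
    """Monoisotopic neutral mass of a derivatized peptidoform.

    Sum of residue masses + water + modification deltas + one propionyl on
    the peptide N-terminus + one propionyl per reactive (un/me1) lysine.
    """
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in p.sequence)
    except KeyError as e:  # pragma: no cover - malformed sequence
        raise ValueError(f"unknown residue {e.args[0]!r}") from e
    mass += MOD_MASS["pr"]  # N-terminal propionyl
    mods = p.mod_dict
    for i, aa in enumerate(p.sequence):
        res = p.start_res + i
        if aa != "K":
            continue
        code = mods.get(res, "un")
        mass += MOD_MASS[code]
        if code in _PROPIONYLATABLE:
            mass += MOD_MASS["pr"]
    from .masses import WATER_MASS

    return mass + WATER_MASS


def compute_mz(p: Peptidoform, charge: int) -> float:
    """m/z (Th) of a peptidoform at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (p.neutral_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class PeptideDefinition:
    """A tryptic peptide with its modifiable residues and allowed codes."""

    histone: str
    sequence: str
    start_res: int
    modifiable: tuple[tuple[int, tuple[str, ...]], ...]

    @property
    def end_res(self) -> int:
        return self.start_res + len(self.sequence) - 1


def build_peptidoform_library(
    histone_spec: list[PeptideDefinition],
) -> list[Peptidoform]:
    """Expand peptide definitions into the full cross-product of peptidoforms.

    Every combination of allowed codes over the modifiable residues yields one
    form, with derivatization applied and neutral mass computed.

    Raises
    ------
    ValueError
        If a modifiable residue lies outside the peptide span, its allowed
        code set is empty, or a code is unknown.
    """
    library: list[Peptidoform] = []
    for pep in histone_spec:
        for res, codes in pep.modifiable:
            if not (pep.start_res <= res <= pep.end_res):
                raise ValueError(
                    f"{pep.histone} residue {res} outside span "
                    f"{pep.start_res}-{pep.end_res}"
                )
            if not codes:
                raise ValueError(f"empty code set for residue {res}")
            for c in codes:
                if c not in KNOWN_CODES:
                    raise ValueError(f"unknown modification code {c!r}")
        residues = [r for r, _ in pep.modifiable]
        for combo in itertools.product(*(codes for _, codes in pep.modifiable)):
            mods = tuple(zip(residues, combo))
            library.append(
                Peptidoform(
                    histone=pep.histone,
                    sequence=pep.sequence,
                    start_res=pep.start_res,
                    end_res=pep.end_res,
                    mods=mods,
                )
            )
    return library


def parse_form_key(key: str) -> tuple[str, int, int, dict[int, str]]:
    """Parse ``histone:start-end:modstring`` into (histone, start, end, mods)."""
    m = _KEY_RE.match(key)
    if m is None:
        raise ValueError(f"malformed peptidoform key {key!r}")
    mods: dict[int, str] = {}
    modstr = m.group("mods")
    if modstr != "unmod":
        for part in modstr.split("."):
            pm = _MOD_RE.match(part)
            if pm is None:
                raise ValueError(f"malformed mod token {part!r} in {key!r}")
            mods[int(pm.group("res"))] = pm.group("code")
    return m.group("histone"), int(m.group("start")), int(m.group("end")), mods


_ME_SET = ("un", "me1", "me2", "me3")
_ME_AC_SET = ("un", "me1", "me2", "me3", "ac")
_AC_SET = ("un", "ac")


def default_histone_library() -> list[Peptidoform]:
    """The default H3/H4 tryptic peptide library used throughout.

    Covers the commonly quantified Arg-C-like peptides from propionylated
    mouse histones H3 and H4: the H3 K4, K9/K14, K18/K23, K27/K36 peptides,
    the H4 aa 4-17 peptide carrying all four acetylatable lysines
    (K5/K8/K12/K16), and the H4 K20 peptide.
    """
    defs = [
        PeptideDefinition("H3", "TKQTAR", 3, ((4, _ME_SET),)),
        PeptideDefinition("H3", "KSTGGKAPR", 9, ((9, _ME_AC_SET), (14, _AC_SET))),
        PeptideDefinition("H3", "KQLATKAAR", 18, ((18, _AC_SET), (23, _AC_SET))),
        PeptideDefinition(
            "H3", "KSAPATGGVKKPHR", 27, ((27, _ME_AC_SET), (36, _ME_SET))
        ),
        PeptideDefinition(
            "H4", "GKGGKGLGKGGAKR", 4,
            ((5, _AC_SET), (8, _AC_SET), (12, _AC_SET), (16, _AC_SET)),
        ),
        PeptideDefinition("H4", "KVLR", 20, ((20, _ME_SET),)),
    ]
    return build_peptidoform_library(defs)
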