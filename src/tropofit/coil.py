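"""Heptad-register annotation of coiled-coil sequences.

A parallel two-stranded coiled-coil repeats every seven residues, labelled
a–g.  Positions a and d form the hydrophobic core between the two helices;
e and g flank the core and can form inter-chain salt bridges (g on one
chain with the following e′ on the partner chain).  Charged residues three
or four apart along one helix sit on adjacent turns and can form
intra-helical ion pairs.  This module assigns the register from user
anchors, classifies residues, locates alanine-type core clusters, detects
the charge pairs above, and reports how a point substitution changes them.

The register is exact cyclic arithmetic: given an anchor residue with a
known letter, every other residue in the same continuous segment is forced.
Anchors that contradict each other within one segment raise
:class:`~tropofit.errors.RegisterConflictError` — a real situation for
tropomyosins whose published per-residue assignments do not always fit a
single continuous heptad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError, RegisterConflictError, ValidationError

__all__ = [
    "HEPTAD_LETTERS",
    "RegisterAnchor",
    "HeptadAnnotation",
    "PairInteraction",
    "MutationReport",
    "assign_register",
    "classify_residues",
    "find_core_clusters",
    "find_pair_interactions",
    "annotate_mutation",
]

HEPTAD_LETTERS = "abcdefg"

#: Core positions of the heptad (hydrophobic seam).
CORE_LETTERS = frozenset("ad")

NEGATIVE = frozenset("DE")
POSITIVE_BASE = frozenset("KR")
HYDROPHOBIC = frozenset("MLIVFWY")
SMALL = frozenset("ASTG")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
POLAR = frozenset("STNQCYHKRDE")


@dataclass(frozen=True)
class RegisterAnchor:
    """A 1-based residue index with a known heptad letter."""

    residue_index: int
    letter: str

    def __post_init__(self):
        if self.letter not in HEPTAD_LETTERS:
            raise ParameterError(f"heptad letter must be one of a-g, got {self.letter!r}")
        if self.residue_index < 1:
            raise ParameterError("residue_index is 1-based and must be ≥ 1")


@dataclass(frozen=True)
class HeptadAnnotation:
    """Per-residue a–g assignment over one or more contiguous segments."""

    sequence: str
    segments: tuple[tuple[int, int, RegisterAnchor], ...]  # (start, end, anchor), 1-based inclusive
    letters: str  # one letter per residue

    def letter_at(self, position: int) -> str:
        """Heptad letter of a 1-based residue position."""
        return self.letters[position - 1]

    def positions_with_letter(self, letter: str) -> list[int]:
        return [i + 1 for i, l in enumerate(self.letters) if l == letter]


@dataclass(frozen=True)
class PairInteraction:
    """A detected residue pair with its electrostatic character."""

    kind: str  # intra_helix_i3 | intra_helix_i4 | interchain_g_e
    residues: tuple[tuple[int, str], tuple[int, str]]
    charge_class: str  # attractive | repulsive | neutral


@dataclass(frozen=True)
class MutationReport:
    """Structural context of a single amino-acid substitution."""

    position: int
    wt_aa: str
    mut_aa: str
    heptad_letter: str
    wt_class: str
    mut_class: str
    pairs_before: tuple[PairInteraction, ...]
    pairs_after: tuple[PairInteraction, ...]
    classification: str  # core-packing | intra-helix-pair | interchain-bridge | surface
    is_noop: bool = False
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        pair = lambda p: {
            "kind": p.kind,
            "residues": [list(r) for r in p.residues],
            "charge_class": p.charge_class,
        }
        return {
            "position": self.position,
            "wt_aa": self.wt_aa,
            "mut_aa": self.mut_aa,
            "heptad_letter": self.heptad_letter,
            "wt_class": self.wt_class,
            "mut_class": self.mut_class,
            "pairs_before": [pair(p) for p in self.pairs_before],
            "pairs_after": [pair(p) for p in self.pairs_after],
            "classification": self.classification,
            "is_noop": self.is_noop,
            "notes": list(self.notes),
        }


def _letter_index(letter: str) -> int:
    return HEPTAD_LETTERS.index(letter)


def letter_from_anchor(anchor: RegisterAnchor, position: int) -> str:
    """Heptad letter forced at ``position`` by cyclic propagation from the anchor."""
    offset = (position - anchor.residue_index) % 7
    return HEPTAD_LETTERS[(_letter_index(anchor.letter) + offset) % 7]


def assign_register(
    sequence: str,
    anchors: list[RegisterAnchor],
    segments: list[tuple[int, int]] | None = None,
) -> HeptadAnnotation:
    """Propagate heptad letters from anchors across contiguous segments.

    With no explicit ``segments`` a single segment spans the whole sequence
    and every anchor must agree on its register; disagreement raises
    :class:`RegisterConflictError` naming the incompatible anchors.  With
    explicit segments (1-based, inclusive, tiling the sequence) each segment
    takes its register from the anchors that fall inside it.
    """
    if not anchors:
        raise ParameterError("at least one register anchor is required")
    n = len(sequence)
    for a in anchors:
        if a.residue_index > n:
            raise ParameterError(f"anchor index {a.residue_index} beyond sequence length {n}")
    if segments is None:
        segments = [(1, n)]
    else:
        segments = sorted(segments)
        covered = []
        for start, end in segments:
            if not (1 <= start <= end <= n):
                raise ParameterError(f"segment ({start}, {end}) outside sequence")
            covered.extend(range(start, end + 1))
        if covered != list(range(1, n + 1)):
            raise ParameterError("segments must tile the sequence without gaps or overlap")

    letters = [None] * n
    seg_out = []
    for start, end in segments:
        inside = [a for a in anchors if start <= a.residue_index <= end]
        if not inside:
            raise ParameterError(f"segment ({start}, {end}) has no anchor")
        ref = inside[0]
        for other in inside[1:]:
            if letter_from_anchor(ref, other.residue_index) != other.letter:
                raise RegisterConflictError(ref, other)
        for pos in range(start, end + 1):
            letters[pos - 1] = letter_from_anchor(ref, pos)
        seg_out.append((start, end, ref))
    return HeptadAnnotation(sequence=sequence, segments=tuple(seg_out), letters="".join(letters))


def classify_residues(annotation: HeptadAnnotation, histidine_positive: bool = True) -> list[str]:
    """Per-residue chemical class.

    Classes: ``charged-`` (D, E), ``charged+`` (K, R, and H unless
    ``histidine_positive`` is off), ``hydrophobic`` (M, L, I, V, F, W, Y),
    ``small`` (A, S, T, G), ``other``.  Every residue receives exactly one
    class.
    """
    positive = POSITIVE_BASE | ({"H"} if histidine_positive else set())
    classes = []
    for aa in annotation.sequence:
        if aa not in STANDARD_AA:
            raise ValidationError(f"unknown residue letter {aa!r}")
        if aa in NEGATIVE:
            classes.append("charged-")
        elif aa in positive:
            classes.append("charged+")
        elif aa in HYDROPHOBIC:
            classes.append("hydrophobic")
        elif aa in SMALL:
            classes.append("small")
        else:
            classes.append("other")
    return classes


def _classify_single(aa: str, histidine_positive: bool = True) -> str:
    positive = POSITIVE_BASE | ({"H"} if histidine_positive else set())
    if aa not in STANDARD_AA:
        raise ValidationError(f"unknown residue letter {aa!r}")
    if aa in NEGATIVE:
        return "charged-"
    if aa in positive:
        return "charged+"
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in SMALL:
        return "small"
    return "other"


def find_core_clusters(annotation: HeptadAnnotation, classes: list[str]) -> list[dict]:
    """Runs of consecutive core (a/d) positions occupied by small residues.

    A cluster is a maximal run of small-class residues along the ordered
    a/d core positions; each cluster is reported with its member positions
    and the flanking runs of hydrophobic-occupied core positions (empty at
    a sequence end).  Single small residues between hydrophobic cores count
    as clusters of size one.
    """
    core = [i + 1 for i, l in enumerate(annotation.letters) if l in CORE_LETTERS]
    clusters = []
    i = 0
    while i < len(core):
        if classes[core[i] - 1] == "small":
            j = i
            while j + 1 < len(core) and classes[core[j + 1] - 1] == "small":
                j += 1
            members = core[i : j + 1]
            left = []
            k = i - 1
            while k >= 0 and classes[core[k] - 1] == "hydrophobic":
                left.append(core[k])
                k -= 1
            right = []
            k = j + 1
            while k < len(core) and classes[core[k] - 1] == "hydrophobic":
                right.append(core[k])
                k += 1
            clusters.append(
                {
                    "members": members,
                    "residues": [annotation.sequence[p - 1] for p in members],
                    "flank_left": list(reversed(left)),
                    "flank_right": right,
                }
            )
            i = j + 1
        else:
            i += 1
    return clusters


def _charge_pair_class(c1: str, c2: str) -> str:
    charged = {"charged-", "charged+"}
    if c1 in charged and c2 in charged:
        return "attractive" if c1 != c2 else "repulsive"
    return "neutral"


def find_pair_interactions(annotation: HeptadAnnotation, classes: list[str]) -> list[PairInteraction]:
    """Enumerate intra-helix (i, i+3)/(i, i+4) charged pairs and g–e′ pairs.

    The molecule is assumed to be an in-register parallel homodimer, so the
    partner chain carries the same sequence and register: a g-position
    residue i pairs across the interface with the e-position residue i+5 of
    the other chain.  Inter-chain pairs are reported for every g position
    (possibly neutral); intra-helix pairs only when both residues are
    charged.
    """
    seq = annotation.sequence
    n = len(seq)
    pairs: list[PairInteraction] = []
    for i in range(1, n + 1):
        for off, kind in ((3, "intra_helix_i3"), (4, "intra_helix_i4")):
            j = i + off
            if j <= n:
                cc = _charge_pair_class(classes[i - 1], classes[j - 1])
                if cc != "neutral":
                    pairs.append(
                        PairInteraction(
                            kind=kind,
                            residues=((i, seq[i - 1]), (j, seq[j - 1])),
                            charge_class=cc,
                        )
                    )
        if annotation.letter_at(i) == "g" and i + 5 <= n:
            j = i + 5
            if annotation.letter_at(j) == "e":  # holds within one segment
                pairs.append(
                    PairInteraction(
                        kind="interchain_g_e",
                        residues=((i, seq[i - 1]), (j, seq[j - 1])),
                        charge_class=_charge_pair_class(classes[i - 1], classes[j - 1]),
                    )
                )
    return pairs


def _pairs_involving(pairs: list[PairInteraction], position: int) -> tuple[PairInteraction, ...]:
    return tuple(p for p in pairs if position in (p.residues[0][0], p.residues[1][0]))


def annotate_mutation(
    annotation: HeptadAnnotation,
    classes: list[str],
    position: int,
    mut_aa: str,
    histidine_positive: bool = True,
) -> MutationReport:
    """Report the structural context of substituting ``mut_aa`` at ``position``.

    Category assignment: ``core-packing`` if and only if the heptad letter
    is a or d; otherwise ``interchain-bridge`` for e/g positions,
    ``intra-helix-pair`` when the residue participates in an intra-helical
    charge pair before or after the substitution, else ``surface``.
    """
    n = len(annotation.sequence)
    if not (1 <= position <= n):
        raise ParameterError(f"position {position} outside sequence of length {n}")
    mut_aa = mut_aa.upper()
    if mut_aa not in STANDARD_AA:
        raise ValidationError(f"unknown residue letter {mut_aa!r}")
    wt_aa = annotation.sequence[position - 1]
    letter = annotation.letter_at(position)
    wt_class = classes[position - 1]
    mut_class = _classify_single(mut_aa, histidine_positive)

    mut_seq = annotation.sequence[: position - 1] + mut_aa + annotation.sequence[position:]
    mut_annotation = HeptadAnnotation(
        sequence=mut_seq, segments=annotation.segments, letters=annotation.letters
    )
    mut_classes = list(classes)
    mut_classes[position - 1] = mut_class

    pairs_before = _pairs_involving(find_pair_interactions(annotation, classes), position)
    pairs_after = _pairs_involving(find_pair_interactions(mut_annotation, mut_classes), position)

    notes = []
    if mut_aa == wt_aa:
        notes.append("synonymous substitution: no-op")
    if wt_class == "small" and mut_class == "small" and wt_aa not in POLAR and mut_aa in POLAR:
        notes.append("small nonpolar → small polar: hydrophilic character introduced")
    ctx_lo, ctx_hi = max(1, position - 1), min(n, position + 1)
    context = annotation.sequence[ctx_lo - 1 : ctx_hi]
    ctx_classes = classes[ctx_lo - 1 : ctx_hi]
    if ctx_classes.count("charged+") >= 2:
        notes.append(f"local context {context} ({ctx_lo}-{ctx_hi}) is arginine/lysine rich")

    if letter in CORE_LETTERS:
        classification = "core-packing"
    elif letter in ("e", "g"):
        classification = "interchain-bridge"
    elif any(p.kind.startswith("intra_helix") for p in pairs_before + pairs_after):
        classification = "intra-helix-pair"
    else:
        classification = "surface"

    return MutationReport(
        position=position,
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        heptad_letter=letter,
        wt_class=wt_class,
        mut_class=mut_class,
        pairs_before=pairs_before,
        pairs_after=pairs_after,
        classification=classification,
        is_noop=mut_aa == wt_aa,
        notes=tuple(notes),
    )
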