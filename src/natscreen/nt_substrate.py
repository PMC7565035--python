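"""Protein N-terminus processing rules.

Implements a deterministic rule engine that (a) decides whether the initiator
methionine (iMet) is removed by methionine aminopeptidase, (b) routes the
resulting N-terminus to an N-terminal acetyltransferase (NAT) complex, and
(c) classifies the functional consequence of a missense substitution within
the first five residues.

Rule table
----------
* iMet is cleaved when the second residue (P2) is small: ``A C G P S T V``.
* After cleavage, the exposed residue is a NatA substrate unless it is
  proline, which blocks acetylation entirely.
* A cleaved N-terminus that starts with the histone motif (default ``SGRG``,
  shared by histones H2A and H4) is handled by NatD and takes precedence
  over generic NatA routing.
* When iMet is retained, acidic/amide P2 residues (``D E N Q``) route to
  NatB; bulky/hydrophobic and basic P2 residues (``L I F W M Y K H``) route
  to the NatC/NatE/NatF group, which is treated as one bucket; the remaining
  retained-Met case (``R``) is left unacetylated.

The retained-Met buckets are a documented completion of partially published
substrate specificities; the bucket granularity matches how "class
preserving" substitutions are counted downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "CLEAVED_P2",
    "NATA_P2",
    "NATB_P2",
    "NATCEF_P2",
    "DEFAULT_HISTONE_MOTIF",
    "NatClass",
    "MutationEffect",
    "NtermSequence",
    "RoutingResult",
    "NtMutationEffect",
    "route_nterm",
    "classify_substitution",
    "classify_motif_mutation",
    "substitution_truth_table",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: P2 residues small enough for methionine-aminopeptidase cleavage of iMet.
CLEAVED_P2 = frozenset("ACGPSTV")

#: Post-cleavage N-terminal residues acetylated by NatA (cleaved set minus P).
NATA_P2 = CLEAVED_P2 - {"P"}

#: Retained-Met P2 residues routed to NatB.
NATB_P2 = frozenset("DENQ")

#: Retained-Met P2 residues routed to the NatC/NatE/NatF bucket.
NATCEF_P2 = frozenset("LIFWMYKH")

#: N-terminal motif (on the cleaved protein) recognised by NatD on histones.
DEFAULT_HISTONE_MOTIF = "SGRG"


class NatClass(str, enum.Enum):
    """Routing outcome for an N-terminus."""

    NatA = "NatA"
    NatB = "NatB"
    NatC_E_F = "NatC_E_F"
    NatD_motif = "NatD_motif"
    unacetylated = "unacetylated"
    blocked = "blocked"


#: Classes that correspond to an actually acetylated N-terminus.
ACETYLATED_CLASSES = frozenset(
    {NatClass.NatA, NatClass.NatB, NatClass.NatC_E_F, NatClass.NatD_motif}
)


class MutationEffect(str, enum.Enum):
    """Consequence of an N-terminal missense substitution."""

    initiator_loss = "initiator_loss"
    preserves_class = "preserves_class"
    changes_class = "changes_class"
    abolishes_ntac = "abolishes_ntac"
    gains_ntac = "gains_ntac"
    motif_disrupting = "motif_disrupting"
    outside_nterm = "outside_nterm"


@dataclass(frozen=True)
class NtermSequence:
    """An N-terminal amino-acid sequence, 1-based positions P1..Pn.

    P1 is expected (but not required) to be the initiator methionine.
    """

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(
                f"N-terminal sequence must have length >= 2, got {len(self.residues)}"
            )
        for i, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"non-standard residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} out of range 1..{len(self.residues)}")
        return self.residues[position - 1]

    def substitute(self, position: int, alt: str) -> "NtermSequence":
        """Return a copy with the residue at 1-based ``position`` replaced."""
        ref = self[position]
        if alt not in AMINO_ACIDS:
            raise ValueError(f"non-standard alternate residue {alt!r}")
        if alt == ref:
            raise ValueError(
                f"alternate residue equals reference {ref!r} at position {position}"
            )
        r = self.residues
        return NtermSequence(r[: position - 1] + alt + r[position:])


@dataclass(frozen=True)
class RoutingResult:
    """NAT-complex assignment for an N-terminal sequence.

    ``acetylated_position`` is 1-based on the *translated* protein including
    iMet: P2 for cleaved substrates (the new N-terminal residue), P1 for
    retained-Met substrates, ``None`` when nothing is acetylated.
    """

    cleaved: bool
    nat_class: NatClass
    acetylated_position: int | None

    @property
    def is_acetylated(self) -> bool:
        return self.nat_class in ACETYLATED_CLASSES


@dataclass(frozen=True)
class NtMutationEffect:
    """Before/after routing comparison for one substitution."""

    effect: MutationEffect
    before: RoutingResult
    after: RoutingResult | None


def _as_seq(seq: NtermSequence | str) -> NtermSequence:
    return seq if isinstance(seq, NtermSequence) else NtermSequence(seq)


def route_nterm(
    seq: NtermSequence | str, motif: str = DEFAULT_HISTONE_MOTIF
) -> RoutingResult:
    """Assign an N-terminal sequence to a NAT class.

    The motif check takes precedence over generic NatA routing: a cleaved
    N-terminus starting with ``motif`` is a NatD substrate even though its
    first residue may also be in the NatA set.
    """
    seq = _as_seq(seq)
    p2 = seq[2]
    if p2 in CLEAVED_P2:
        post_cleavage = seq.residues[1:]
        if post_cleavage.startswith(motif):
            return RoutingResult(cleaved=True, nat_class=NatClass.NatD_motif,
                                 acetylated_position=2)
        if p2 == "P":
            return RoutingResult(cleaved=True, nat_class=NatClass.blocked,
                                 acetylated_position=None)
        return RoutingResult(cleaved=True, nat_class=NatClass.NatA,
                             acetylated_position=2)
    if p2 in NATB_P2:
        return RoutingResult(cleaved=False, nat_class=NatClass.NatB,
                             acetylated_position=1)
    if p2 in NATCEF_P2:
        return RoutingResult(cleaved=False, nat_class=NatClass.NatC_E_F,
                             acetylated_position=1)
    # Retained Met with no known NAT for the exposed context (P2 = R).
    return RoutingResult(cleaved=False, nat_class=NatClass.unacetylated,
                         acetylated_position=None)


def _compare_routing(before: RoutingResult, after: RoutingResult) -> MutationEffect:
    if before.nat_class == NatClass.NatD_motif and after.nat_class != NatClass.NatD_motif:
        return MutationEffect.motif_disrupting
    if before.nat_class == after.nat_class:
        return MutationEffect.preserves_class
    if before.is_acetylated and after.is_acetylated:
        return MutationEffect.changes_class
    if before.is_acetylated and not after.is_acetylated:
        return MutationEffect.abolishes_ntac
    if not before.is_acetylated and after.is_acetylated:
        return MutationEffect.gains_ntac
    # blocked <-> unacetylated: no acetylation either way, label changed.
    return MutationEffect.changes_class


def classify_substitution(
    seq: NtermSequence | str,
    position: int,
    alt: str,
    motif: str = DEFAULT_HISTONE_MOTIF,
) -> NtMutationEffect:
    """Classify a missense substitution within a protein N-terminus.

    * P1 substitutions of the initiator methionine are always
      ``initiator_loss`` — loss of the start codon is a loss-of-function
      event and is never interpreted through routing.
    * Positions beyond P5 are ``outside_nterm``.
    * Otherwise the sequence is routed before and after the substitution and
      the NAT classes compared.
    """
    seq = _as_seq(seq)
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} out of range 1..{len(seq)}")
    ref = seq[position]
    if alt not in AMINO_ACIDS:
        raise ValueError(f"non-standard alternate residue {alt!r}")
    if alt == ref:
        raise ValueError(f"alternate residue equals reference {ref!r}")

    before = route_nterm(seq, motif=motif)
    if position == 1 and ref == "M":
        return NtMutationEffect(MutationEffect.initiator_loss, before, None)
    after = route_nterm(seq.substitute(position, alt), motif=motif)
    if position > 5:
        return NtMutationEffect(MutationEffect.outside_nterm, before, after)
    return NtMutationEffect(_compare_routing(before, after), before, after)


def classify_motif_mutation(
    histone_nterm: NtermSequence | str,
    position: int,
    alt: str,
    motif: str = DEFAULT_HISTONE_MOTIF,
) -> NtMutationEffect:
    """Classify a substitution on a histone-motif substrate.

    ``position`` is 1-based on the *cleaved* protein (the motif serine is
    position 1). Any substitution inside the motif is ``motif_disrupting``;
    positions past the motif are ``outside_nterm``.
    """
    seq = _as_seq(histone_nterm)
    before = route_nterm(seq, motif=motif)
    if before.nat_class != NatClass.NatD_motif:
        raise ValueError(
            "sequence does not match the histone motif after cleavage: "
            f"{seq.residues[:8]!r} (motif {motif!r})"
        )
    if position < 1 or position + 1 > len(seq):
        raise ValueError(f"cleaved position {position} out of range")
    # Position on the original (uncleaved) translated protein.
    full_position = position + 1
    after = route_nterm(seq.substitute(full_position, alt), motif=motif)
    if position > len(motif):
        return NtMutationEffect(MutationEffect.outside_nterm, before, after)
    return NtMutationEffect(MutationEffect.motif_disrupting, before, after)


def substitution_truth_table(motif: str = DEFAULT_HISTONE_MOTIF) -> pd.DataFrame:
    """Exhaustive 20 x 19 table of P2 substitution effects.

    Each row gives (ref, alt, effect) for a P2 substitution on a generic
    non-motif backbone. Agrees row-for-row with :func:`classify_substitution`.
    """
    rows = []
    for ref in sorted(AMINO_ACIDS):
        # Backbone chosen so no ref residue accidentally forms the motif.
        backbone = NtermSequence("M" + ref + "LKLK")
        for alt in sorted(AMINO_ACIDS - {ref}):
            result = classify_substitution(backbone, 2, alt, motif=motif)
            rows.append({"ref": ref, "alt": alt, "effect": result.effect.value})
    return pd.DataFrame(rows, columns=["ref", "alt", "effect"])
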