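"""sgRNA-target pair representation and sequence annotations.

The screening unit is a pair of a 20-nt spacer (the guide segment of an
sgRNA, RNA alphabet) and a 30-nt integrated target context laid out as::

    [4 nt upstream][20 nt protospacer][3 nt PAM][3 nt downstream]

Mismatch positions are reported in PAM-anchored numbering: position 1 is
the protospacer base adjacent to the PAM, position 20 is the PAM-distal
(5'-most) base. A helper converts to 5'-anchored numbering for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DNA_ALPHABET",
    "GuideTargetPair",
    "MismatchAnnotation",
    "classify_pam",
    "annotate_mismatches",
    "pam_distal_run",
    "pam_anchored_to_five_prime",
    "write_library_tsv",
    "read_library_tsv",
    "write_context_fasta",
]

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

EXPRESSION_SYSTEMS = ("gN19", "GN19", "tRNA_N20")

# context layout offsets (0-based, half-open)
UPSTREAM_SLICE = slice(0, 4)
PROTOSPACER_SLICE = slice(4, 24)
PAM_SLICE = slice(24, 27)
DOWNSTREAM_SLICE = slice(27, 30)

PURINES = frozenset("AG")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class ShapeError(ValueError):
    """A sequence has the wrong length for the requested operation."""


@dataclass(frozen=True)
class MismatchAnnotation:
    """One spacer/protospacer difference.

    position_pam counts 1 at the PAM-proximal protospacer base and 20 at
    the PAM-distal (5') end. ``mclass`` follows the base-pairing geometry
    with the target strand: a spacer G over a protospacer A makes an
    rG:dT wobble, a spacer U over a protospacer C makes an rU:dG wobble;
    other purine<->purine / pyrimidine<->pyrimidine substitutions are
    non-wobble transitions; purine<->pyrimidine swaps are transversions.
    ``five_prime_g`` marks the obligatory 5' G of a U6-transcribed gN19
    guide, an expression-system artifact rather than a designed mismatch.
    """

    position_pam: int
    spacer_base: str
    protospacer_base: str
    mclass: str
    five_prime_g: bool = False


@dataclass
class GuideTargetPair:
    pair_id: str
    spacer: str
    context: str
    pam4: str
    expression_system: str
    mismatches: list[MismatchAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ShapeError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if len(self.context) != 30:
            raise ShapeError(f"context must be 30 nt, got {len(self.context)}")
        if set(self.spacer.upper()) - RNA_ALPHABET:
            raise AlphabetError(f"spacer has non-ACGU characters: {self.spacer}")
        if set(self.context.upper()) - DNA_ALPHABET:
            raise AlphabetError(f"context has non-ACGT characters: {self.context}")
        if self.expression_system not in EXPRESSION_SYSTEMS:
            raise ValueError(
                f"expression_system must be one of {EXPRESSION_SYSTEMS}, "
                f"got {self.expression_system!r}"
            )

    @property
    def protospacer(self) -> str:
        return self.context[PROTOSPACER_SLICE]

    @property
    def pam(self) -> str:
        return self.context[PAM_SLICE]

    @property
    def pam_class(self) -> str:
        return classify_pam(self.pam)

    def n_designed_mismatches(self) -> int:
        """Mismatch count excluding the gN19 5'-G artifact."""
        return sum(1 for m in self.mismatches if not m.five_prime_g)


def classify_pam(pam: str) -> str:
    """Partition a 3-nt PAM into NGG / NGH / nonNG.

    NGG: second and third base G. NGH: second base G, third base A/C/T.
    nonNG: second base not G. The three classes tile all 64 3-nt PAMs
    (4 + 12 + 48).
    """
    if len(pam) != 3:
        raise ShapeError(f"PAM must be 3 nt, got {pam!r}")
    pam = pam.upper()
    if set(pam) - DNA_ALPHABET:
        raise AlphabetError(f"PAM has non-ACGT characters: {pam!r}")
    if pam[1] != "G":
        return "nonNG"
    return "NGG" if pam[2] == "G" else "NGH"


def _mismatch_class(spacer_base: str, protospacer_base: str) -> str:
    s, p = spacer_base.upper().replace("T", "U"), protospacer_base.upper()
    if (s == "G" and p == "A") or (s == "U" and p == "C"):
        return "wobble"
    s_dna = s.replace("U", "T")
    if (s_dna, p) in _TRANSITIONS:
        return "nonwobble_transition"
    return "transversion"


def annotate_mismatches(
    spacer: str, protospacer: str, expression_system: str = "GN19"
) -> list[MismatchAnnotation]:
    """Annotate every position where the spacer (U read as T) differs
    from the protospacer.

    Positions are PAM-anchored (1 adjacent to the PAM). For a gN19
    expression system, a difference at position 20 whose spacer base is G
    is flagged ``five_prime_g`` and excluded from designed-mismatch
    counts downstream.
    """
    if len(spacer) != 20 or len(protospacer) != 20:
        raise ShapeError(
            f"spacer and protospacer must both be 20 nt, got "
            f"{len(spacer)} and {len(protospacer)}"
        )
    spacer_u = spacer.upper()
    proto_u = protospacer.upper()
    if set(spacer_u) - RNA_ALPHABET - {"T"}:
        raise AlphabetError(f"spacer has unexpected characters: {spacer!r}")
    if set(proto_u) - DNA_ALPHABET:
        raise AlphabetError(f"protospacer has non-ACGT characters: {protospacer!r}")

    annotations: list[MismatchAnnotation] = []
    for i in range(20):  # i = 0 is the 5' end => PAM-anchored position 20 - i
        s = spacer_u[i].replace("T", "U")
        p = proto_u[i]
        if s.replace("U", "T") == p:
            continue
        position_pam = 20 - i
        is_5pg = (
            expression_system == "gN19" and position_pam == 20 and s == "G"
        )
        annotations.append(
            MismatchAnnotation(
                position_pam=position_pam,
                spacer_base=s,
                protospacer_base=p,
                mclass=_mismatch_class(s, p),
                five_prime_g=is_5pg,
            )
        )
    # PAM-proximal first for stable reporting
    annotations.sort(key=lambda a: a.position_pam)
    return annotations


def pam_distal_run(mismatches: Iterable[MismatchAnnotation]) -> int:
    """Length of the consecutive mismatch run anchored at the PAM-distal
    end (position 20 inward); 0 when position 20 matches.

    This is the n_PD statistic used to compare unwinding specificity of
    Cas9 variants against targets with increasing PAM-distal mismatch
    runs. The gN19 5'-G artifact does not count.
    """
    positions = {m.position_pam for m in mismatches if not m.five_prime_g}
    n = 0
    while (20 - n) in positions:
        n += 1
    return n


def pam_anchored_to_five_prime(position_pam: int) -> int:
    """Convert PAM-anchored position (1 = next to PAM) to 5'-anchored."""
    if not 1 <= position_pam <= 20:
        raise ValueError(f"position must be in 1..20, got {position_pam}")
    return 21 - position_pam


# ---------------------------------------------------------------------------
# External interfaces: TSV library tables and FASTA context export


def write_library_tsv(pairs: Sequence[GuideTargetPair], path) -> None:
    import pandas as pd

    rows = []
    for p in pairs:
        spec = ";".join(
            f"{m.position_pam}:{m.spacer_base}>{m.protospacer_base}:{m.mclass}"
            + (":5pg" if m.five_prime_g else "")
            for m in p.mismatches
        )
        rows.append(
            {
                "pair_id": p.pair_id,
                "spacer": p.spacer,
                "context30": p.context,
                "pam4": p.pam4,
                "expression_system": p.expression_system,
                "designed_mismatch_spec": spec,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> list[GuideTargetPair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = []
    for row in df.itertuples(index=False):
        pair = GuideTargetPair(
            pair_id=str(row.pair_id),
            spacer=row.spacer,
            context=row.context30,
            pam4=row.pam4,
            expression_system=row.expression_system,
        )
        pair.mismatches = annotate_mismatches(
            pair.spacer, pair.protospacer, pair.expression_system
        )
        pairs.append(pair)
    return pairs


def write_context_fasta(pairs: Sequence[GuideTargetPair], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(p.context), id=p.pair_id, description="")
        for p in pairs
    ]
    seqio_write(records, str(path), "fasta")
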