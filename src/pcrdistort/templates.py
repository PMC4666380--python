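"""Amplicon templates and synthetic input pools.

The experimental system is a pool of barcode-pair amplicons: two 20-nt
random barcodes flanking the 46-nt PhiC31 AttL constant region, followed
by a 15-nt varietal tag (a UMI) ligated before PCR.  The sequenced region
is therefore 101 nt: barcode (20) + AttL (46) + barcode (20) + tag (15).

Three barcode-pair classes exist.  BC1 and BC2 have balanced base
composition but carry purine/pyrimidine "anchor" positions (R = A/G,
Y = C/T) in complementary patterns, which later lets chimeric BC1-BC2
pairs be recognised.  BC3 barcodes are GC-rich (S = G/C codes, expected
GC content 0.80) and carry no R/Y anchors.

Anchor positions are parsed from the template strings, never hard-coded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng

# Oligo designs (IUPAC), 5'->3': Illumina P5/SBS3 prefix, barcode 1, AttL,
# barcode 2.  The 15-nt varietal tag of the ligated adapter is appended as
# N's so that the template spans the full sequenced region.
_PREFIX = "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
_ATTL = "ACGCCCCCAACTGAGAGAACTCAAGGGCACGCCCTGGCACCCGCAC"
_BARCODES = {
    "BC1-BC1": ("NRNNNNNYYNNNNRRNNNYY", "RRNNNYYNNNNRRNNNNNYN"),
    "BC2-BC2": ("NYNNNNNRRNNNNYYNNNRR", "YYNNNRRNNNNYYNNNNNRN"),
    "BC3-BC3": ("SNSNSNSSSNSSSNSNSNSN", "SNSNSNSSSNSSSNSNSNSN"),
}

IUPAC_CHOICES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "N": "ACGT",
    "R": "AG",
    "Y": "CT",
    "S": "GC",
}

BARCODE_LEN = 20
CONSTANT_LEN = 46
TAG_LEN = 15
READ_LEN = 2 * BARCODE_LEN + CONSTANT_LEN + TAG_LEN  # 101

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class AmpliconTemplate:
    """Parsed layout of one barcode-pair amplicon design.

    Intervals are 0-based half-open over ``full_sequence``.
    ``anchor_positions`` lists ``(barcode_index, offset, symbol)`` for every
    degenerate-but-constrained position (symbol R, Y or S), with the offset
    relative to the start of that barcode slot.
    """

    name: str
    full_sequence: str
    read_region: tuple[int, int]
    barcode_slots: tuple[tuple[int, int], tuple[int, int]]
    constant_region: tuple[int, int]
    tag_slot: tuple[int, int]
    anchor_positions: tuple[tuple[int, int, str], ...] = field(default=())

    @property
    def constant_sequence(self) -> str:
        a, b = self.constant_region
        return self.full_sequence[a:b]

    @property
    def barcode_templates(self) -> tuple[str, str]:
        return tuple(
            self.full_sequence[a:b] for a, b in self.barcode_slots
        )  # type: ignore[return-value]

    def anchors_in_slot(self, slot: int) -> list[tuple[int, str]]:
        """(offset, symbol) pairs of constrained positions in one barcode slot."""
        return [(off, sym) for idx, off, sym in self.anchor_positions if idx == slot]

    def dinucleotide_anchors(self, slot: int) -> list[tuple[int, int]]:
        """Offset pairs of adjacent constrained positions (the dinucleotide anchors)."""
        offsets = sorted(off for off, sym in self.anchors_in_slot(slot) if sym in "RY")
        return [
            (offsets[i], offsets[i + 1])
            for i in range(len(offsets) - 1)
            if offsets[i + 1] == offsets[i] + 1
        ]


def parse_template(name: str, oligo: str) -> AmpliconTemplate:
    """Build an :class:`AmpliconTemplate` from an IUPAC oligo design string.

    The oligo must contain prefix + barcode(20) + AttL(46) + barcode(20);
    the 15-nt tag slot is appended.  Anchors are discovered by scanning the
    barcode slots for R/Y/S codes.
    """
    oligo = oligo.replace(" ", "").upper()
    bad = [(i, ch) for i, ch in enumerate(oligo) if ch not in IUPAC_CHOICES]
    if bad:
        i, ch = bad[0]
        raise ValueError(f"unsupported IUPAC code {ch!r} at position {i} in {name}")
    first_degenerate = next(
        (i for i, ch in enumerate(oligo) if ch not in "ACGT"), None
    )
    if first_degenerate is None:
        raise ValueError(f"{name}: no barcode region found (no degenerate codes)")
    b1 = (first_degenerate, first_degenerate + BARCODE_LEN)
    const = (b1[1], b1[1] + CONSTANT_LEN)
    b2 = (const[1], const[1] + BARCODE_LEN)
    if b2[1] > len(oligo):
        raise ValueError(f"{name}: oligo too short for barcode/AttL/barcode layout")
    constant_seq = oligo[const[0] : const[1]]
    if any(ch not in "ACGT" for ch in constant_seq):
        raise ValueError(f"{name}: constant region contains degenerate codes")
    full = oligo[: b2[1]] + "N" * TAG_LEN
    tag = (b2[1], b2[1] + TAG_LEN)
    anchors = []
    for slot, (a, b) in enumerate((b1, b2)):
        for off, ch in enumerate(full[a:b]):
            if ch in "RYS":
                anchors.append((slot, off, ch))
    return AmpliconTemplate(
        name=name,
        full_sequence=full,
        read_region=(b1[0], tag[1]),
        barcode_slots=(b1, b2),
        constant_region=const,
        tag_slot=tag,
        anchor_positions=tuple(anchors),
    )


def default_templates() -> dict[str, AmpliconTemplate]:
    """The three published amplicon designs, parsed."""
    return {
        name: parse_template(name, _PREFIX + bc1 + _ATTL + bc2)
        for name, (bc1, bc2) in _BARCODES.items()
    }


@dataclass(frozen=True)
class InputMolecule:
    """One pre-PCR molecule: a 40-nt barcode pair plus its varietal tag."""

    barcode_pair: str
    tag: str
    class_pair: tuple[str, str]
    copy_number_before_pcr: int = 1


def expand_iupac_template(template: str, rng) -> str:
    """Draw one concrete DNA sequence from an IUPAC string.

    N is uniform over ACGT, R over AG, Y over CT, S over GC; fixed bases
    are copied verbatim.
    """
    rng = as_rng(rng)
    out = []
    for i, ch in enumerate(template):
        choices = IUPAC_CHOICES.get(ch)
        if choices is None:
            raise ValueError(f"unsupported IUPAC code {ch!r} at position {i}")
        out.append(choices if len(choices) == 1 else choices[rng.integers(len(choices))])
    return "".join(out)


_CLASS_SHORT = {"BC1-BC1": "BC1", "BC2-BC2": "BC2", "BC3-BC3": "BC3"}


def build_input_pool(
    n_molecules: int,
    class_mix: dict[str, float],
    rng,
    templates: dict[str, AmpliconTemplate] | None = None,
) -> list[InputMolecule]:
    """Generate the pre-PCR pool: every molecule single-copy, classes drawn
    from ``class_mix`` (proportions over the template names), barcodes and
    tags expanded from the class templates.
    """
    rng = as_rng(rng)
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    templates = templates or default_templates()
    names = sorted(class_mix)
    probs = np.asarray([class_mix[n] for n in names], dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_mix proportions must be >= 0 and sum to 1")
    draws = rng.choice(len(names), size=n_molecules, p=probs)
    pool = []
    for d in draws:
        name = names[d]
        t = templates[name]
        bc1, bc2 = (expand_iupac_template(b, rng) for b in t.barcode_templates)
        tag = expand_iupac_template("N" * TAG_LEN, rng)
        short = _CLASS_SHORT.get(name, name)
        pool.append(InputMolecule(bc1 + bc2, tag, (short, short)))
    return pool


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_region_sequence(barcode_pair: str, tag: str, template: AmpliconTemplate) -> str:
    """Assemble the 101-nt sequenced region from a barcode pair and tag."""
    return (
        barcode_pair[:BARCODE_LEN]
        + template.constant_sequence
        + barcode_pair[BARCODE_LEN:]
        + tag
    )


def _inject_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        alt = bases[bases != arr[i]]
        arr[i] = alt[rng.integers(3)]
    return arr.tobytes().decode()


def emit_read_pairs(
    rows: pd.DataFrame,
    template: AmpliconTemplate,
    r1_path,
    r2_path,
    rng,
    seq_error_rate: float = 0.0,
    read_length: int = READ_LEN,
    phred: int = 30,
    truth_path=None,
) -> pd.DataFrame:
    """Write paired-end FASTQ for a table of sequenced molecules.

    ``rows`` needs columns ``sequence`` (40-nt barcode pair), ``tag``,
    ``read_count`` and optionally ``origin`` and ``true_copies``.  R1 is the
    forward 101-nt region, R2 its reverse complement; each read carries
    independent per-base substitution errors at ``seq_error_rate``.
    Returns the ground-truth table (also written to ``truth_path`` as TSV
    when given).
    """
    rng = as_rng(rng)
    if not 0 <= seq_error_rate <= 0.25:
        raise ValueError("seq_error_rate must be in [0, 0.25]")
    region_len = template.read_region[1] - template.read_region[0]
    if read_length != region_len:
        raise ValueError(
            f"read_length {read_length} != template read region length {region_len}"
        )
    qual = chr(33 + phred) * read_length

    def _open(path):
        path = str(path)
        if path.endswith(".gz"):
            return gzip.open(path, "wt")
        return open(path, "w")

    truth_rows = []
    n = 0
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for row in rows.itertuples(index=False):
            source = read_region_sequence(row.sequence, row.tag, template)
            origin = getattr(row, "origin", "input")
            true_copies = getattr(row, "true_copies", 1)
            truth_rows.append(
                (row.sequence, getattr(row, "class_pair", ""), row.tag, origin,
                 true_copies, row.read_count)
            )
            for _ in range(int(row.read_count)):
                n += 1
                r1 = _inject_errors(source, seq_error_rate, rng)
                r2 = _inject_errors(reverse_complement(source), seq_error_rate, rng)
                f1.write(f"@read{n}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@read{n}/2\n{r2}\n+\n{qual}\n")
    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence", "class_pair", "tag", "origin", "true_copies", "read_count"],
    )
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth
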