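"""Template-switch (chimera) detection and the per-molecule switch rate.

BC1 and BC2 barcodes carry complementary purine/pyrimidine anchor
patterns.  A barcode whose anchors all match BC1's pattern is a BC1
barcode, likewise BC2; anything else (e.g. a mixed RY dinucleotide) is
unclassifiable.  A BC1-BC2 or BC2-BC1 pair cannot exist in the input pool
and must come from a template switch across the constant region -- this
detects switches *between* classes, i.e. half of all switches under an
even class mix.

Switching is modelled as a bimolecular collision: the expected number of
new chimeras on cycle j is ``s0 * N_j^2``.  The per-molecule rate is
estimated from the read ratio J_k of detected chimeras to input pairs as
``s0 = 2 * J_k / (N0 * c^(k+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import as_rng, sample_observed_reads
from .preprocess import CountTable
from .profiles import RankProfile, build_profile
from .templates import BARCODE_LEN, AmpliconTemplate, default_templates


def _anchor_matrix(templates: dict[str, AmpliconTemplate], slot: int):
    """Anchor offsets plus the BC1/BC2 purine-pyrimidine patterns for a slot."""
    t1, t2 = templates["BC1-BC1"], templates["BC2-BC2"]
    a1 = dict(t1.anchors_in_slot(slot))
    a2 = dict(t2.anchors_in_slot(slot))
    offsets = sorted(a1)
    if sorted(a2) != offsets:
        raise ValueError("BC1/BC2 anchor offsets disagree; templates inconsistent")
    pat1 = np.array([a1[o] == "R" for o in offsets])  # True = purine expected
    pat2 = np.array([a2[o] == "R" for o in offsets])
    return np.array(offsets), pat1, pat2


def classify_barcode(
    bc: str, templates: dict[str, AmpliconTemplate] | None = None, slot: int = 0
) -> str | None:
    """BC1, BC2 or None (unclassifiable) for one 20-nt barcode in a slot."""
    templates = templates or default_templates()
    if len(bc) != BARCODE_LEN:
        raise ValueError("barcode must be 20 nt")
    offsets, pat1, pat2 = _anchor_matrix(templates, slot)
    purine = np.array([bc[o] in "AG" for o in offsets])
    if (purine == pat1).all():
        return "BC1"
    if (purine == pat2).all():
        return "BC2"
    return None


def classify_pairs(
    sequences, templates: dict[str, AmpliconTemplate] | None = None
) -> list[tuple[str | None, str | None]]:
    """Vectorised classification of 40-nt barcode pairs into slot classes."""
    templates = templates or default_templates()
    seqs = list(sequences)
    if not seqs:
        return []
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), 2 * BARCODE_LEN
    )
    is_purine = (arr == ord("A")) | (arr == ord("G"))
    out = []
    per_slot = []
    for slot in range(2):
        offsets, pat1, pat2 = _anchor_matrix(templates, slot)
        cols = is_purine[:, offsets + slot * BARCODE_LEN]
        m1 = (cols == pat1[None, :]).all(axis=1)
        m2 = (cols == pat2[None, :]).all(axis=1)
        per_slot.append(np.where(m1, 1, np.where(m2, 2, 0)))
    code = {0: None, 1: "BC1", 2: "BC2"}
    for c1, c2 in zip(per_slot[0], per_slot[1]):
        out.append((code[int(c1)], code[int(c2)]))
    return out


def assign_classes(
    table: CountTable, templates: dict[str, AmpliconTemplate] | None = None
) -> CountTable:
    """Add/overwrite the ``class_pair`` column of a count table."""
    table.df["class_pair"] = classify_pairs(table.df["sequence"], templates)
    return table


def detect_chimeras(
    table: CountTable | pd.DataFrame, profile: RankProfile | None = None
) -> pd.DataFrame:
    """Rows whose class pair is BC1-BC2 or BC2-BC1 (between-class chimeras).

    Rows with any unclassifiable barcode are ignored (every anchor must be
    cleanly RR or YY).  If a profile is given, scaled ranks are attached.
    """
    df = table.df if isinstance(table, CountTable) else table
    if "class_pair" not in df.columns:
        raise ValueError("classes not assigned; call assign_classes first")
    pairs = df["class_pair"]
    mask = pairs.map(lambda c: c in (("BC1", "BC2"), ("BC2", "BC1")))
    out = df.loc[mask].copy()
    if profile is not None:
        ranks = pd.Series(
            profile.scaled_rank, index=profile.df["sequence"]
        )
        out["scaled_rank"] = out["sequence"].map(ranks)
    return out


def chimera_read_ratio(df: pd.DataFrame) -> float:
    """J_k: reads of detected chimeras over reads of input-class pairs.

    Input pairs are the intra-class rows (BC1-BC1 / BC2-BC2); BC3 and
    unclassifiable rows are excluded.
    """
    reads = df["reads"] if "reads" in df.columns else df["read_count"]
    pairs = df["class_pair"]
    chim = pairs.map(lambda c: c in (("BC1", "BC2"), ("BC2", "BC1")))
    intra = pairs.map(lambda c: c in (("BC1", "BC1"), ("BC2", "BC2")))
    input_reads = reads[intra].sum()
    if input_reads == 0:
        raise ValueError("no input-class reads; cannot form the read ratio")
    return float(reads[chim].sum() / input_reads)


def estimate_s0(J_k: float, N0: int, c: float = 1.9, k: int = 25) -> float:
    """Per-molecule switch probability from the detected-chimera read ratio.

    The between-class rate is ``J_k / (N0 c^(k+1))``; since only half of
    all switches are between classes under an even mix, s0 is double that.
    """
    if J_k < 0:
        raise ValueError("J_k must be >= 0")
    if N0 < 1:
        raise ValueError("N0 must be >= 1")
    if c <= 1.0:
        raise ValueError("PCR efficiency c must be > 1")
    return 2.0 * J_k / (N0 * c ** (k + 1))


@dataclass
class SwitchLoad:
    per_cycle: np.ndarray  # expected new switches S_j, j = 1..m
    q_exact: float  # exact per-cycle accumulation
    q_closed: float  # closed-form approximation
    regime_ok: bool  # s0 * N_m << 1


def predict_switch_load(s0: float, N0: int, m: int, c: float = 2.0) -> SwitchLoad:
    """Expected switch load after ``m`` cycles of efficiency-``c`` PCR.

    ``S_j = s0 (N0 c^j)^2``; accumulated with growth ``c^(m-j)`` this gives
    ``Q_m = s0 N0^2 c^m sum_j c^j`` exactly, approximated by the closed
    form ``s0 N0^2 c^(2m+1) / (c - 1)`` (``s0 N0^2 2^(2m+1)`` at c = 2).
    """
    j = np.arange(1, m + 1)
    n_j = N0 * c**j
    s_j = s0 * n_j**2
    q_exact = float(np.sum(s_j * c ** (m - j)))
    q_closed = s0 * N0**2 * c ** (2 * m + 1) / (c - 1.0)
    return SwitchLoad(
        per_cycle=s_j,
        q_exact=q_exact,
        q_closed=q_closed,
        regime_ok=bool(s0 * n_j[-1] < 0.01),
    )


def simulate_switching_pcr(
    s0: float,
    sequencing_model,
    rng,
    N0: int = 2900,
    cycles: int = 25,
    class_mix: tuple[float, float] = (0.5, 0.5),
    deterministic_events: bool = False,
) -> RankProfile:
    """Template switching on a background of perfect (doubling) PCR.

    Inputs double every cycle; on cycle j, ``Poisson(s0 N_j^2)`` chimeras
    are born (expectation if ``deterministic_events``) and double
    thereafter.  Only rows that receive at least one sequencing read are
    materialised, which keeps late-cycle chimera cohorts (potentially
    millions of single-copy molecules) tractable.  Chimera class pairs are
    drawn from independent parents under ``class_mix`` (BC1, BC2), so a
    fraction ``2 p (1-p)`` is between-class.  Ground-truth totals are in
    ``profile.df.attrs``.
    """
    rng = as_rng(rng)
    input_copies = 2.0**cycles
    lam = sequencing_model.solve_lam(np.full(N0, input_copies))
    rows = []
    input_reads = rng.poisson(lam * input_copies, size=N0)
    for i, r in enumerate(input_reads):
        if r > 0:
            cls = "BC1" if rng.random() < class_mix[0] else "BC2"
            rows.append((f"in_{i:06d}", r, "input", 0, (cls, cls)))
    q_total = 0.0
    born_total = 0.0
    for j in range(1, cycles + 1):
        n_j = N0 * 2.0**j
        expected = s0 * n_j**2
        n_born = (
            int(round(expected)) if deterministic_events else int(rng.poisson(expected))
        )
        born_total += n_born
        copies = 2.0 ** (cycles - j)
        q_total += n_born * copies
        reads = sample_observed_reads(n_born, lam * copies, rng)
        for m, r in enumerate(reads):
            c1 = "BC1" if rng.random() < class_mix[0] else "BC2"
            c2 = "BC1" if rng.random() < class_mix[0] else "BC2"
            rows.append((f"sw_{j:02d}_{m:06d}", r, "switch", j, (c1, c2)))
    df = pd.DataFrame(
        rows, columns=["sequence", "reads", "origin", "birth_cycle", "class_pair"]
    )
    profile = build_profile(df)
    profile.df.attrs.update(
        {
            "lam": lam,
            "true_switch_molecules": q_total,
            "true_switches_born": born_total,
            "input_molecules": N0 * input_copies,
        }
    )
    return profile
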