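"""Generative forward model of PCR on an input pool.

Tracks per-sequence molecule counts through the cycles.  Per cycle, every
molecule is duplicated with probability ``P_amp`` (binomial increments,
the Galton-Watson branching process); new sequences arise from

* template switches: bimolecular collisions, expected ``s0 * N_j^2`` per
  cycle, realised by crossing the first barcode of one molecule with the
  second barcode of another (partners drawn proportional to current copy
  number), and
* polymerase errors: expected ``e * N_{j-1}`` per cycle, realised as a
  single substitution at a uniformly chosen position of the 40 barcode
  nucleotides of a parent drawn proportional to copy number.

Event counts are Poisson draws around those expectations by default;
``deterministic_events=True`` uses the rounded expectations instead.
Sequencing is modelled as Poisson sampling of the final molecule counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng
from .templates import BARCODE_LEN, InputMolecule


@dataclass
class PcrConfig:
    """Parameters of one simulated PCR: cycle count j, per-cycle
    amplification probability P_amp, per-molecule switch probability s0 and
    per-molecule per-cycle error probability e."""

    cycles: int = 25
    p_amp: float = 0.9
    efficiency_mode: str = "constant"  # "constant" | "by_gc"
    s0: float = 0.0
    e_molecule: float = 0.0
    seed: int | None = None
    deterministic_events: bool = False

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 < self.p_amp <= 1.0:
            raise ValueError("p_amp must be in (0, 1]")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0.0 <= self.e_molecule < 1.0:
            raise ValueError("e_molecule must be in [0, 1)")
        if self.efficiency_mode not in ("constant", "by_gc"):
            raise ValueError("efficiency_mode must be 'constant' or 'by_gc'")


@dataclass
class SequencingModel:
    """Poisson sequencing: reads_i ~ Poisson(lam * copies_i).

    If ``target_plateau_reads`` is set, lam is solved so that the expected
    read sum over the plateau window (the ``plateau_size`` largest copy
    numbers) equals the target.
    """

    lam: float | None = None
    target_plateau_reads: float | None = None
    plateau_size: int = 2900

    def solve_lam(self, copies: np.ndarray) -> float:
        if self.target_plateau_reads is None:
            if self.lam is None or self.lam <= 0:
                raise ValueError("either lam > 0 or target_plateau_reads is required")
            return float(self.lam)
        copies = np.asarray(copies, dtype=float)
        top = np.sort(copies)[::-1][: self.plateau_size]
        total = top.sum()
        if total <= 0:
            raise ValueError("cannot solve lam: all copy numbers are zero")
        return float(self.target_plateau_reads) / total


def simulate_galton_watson(n_founders: int, cfg: PcrConfig, rng) -> np.ndarray:
    """Final copy number per founder under pure stochastic amplification.

    Requires constant efficiency and no switch/error events (those belong
    to :func:`simulate_full_pcr`).
    """
    if cfg.efficiency_mode != "constant" or cfg.s0 != 0 or cfg.e_molecule != 0:
        raise ValueError("simulate_galton_watson requires constant efficiency, s0=e=0")
    rng = as_rng(rng)
    n = np.ones(int(n_founders), dtype=np.int64)
    for _ in range(cfg.cycles):
        n = n + rng.binomial(n, cfg.p_amp)
    return n


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _substitute(seq: str, rng) -> str:
    pos = int(rng.integers(len(seq)))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    alt = _BASES[_BASES != arr[pos]]
    arr[pos] = alt[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_full_pcr(
    pool: list[InputMolecule], cfg: PcrConfig, rng
) -> pd.DataFrame:
    """Cycle-by-cycle simulation with switching and errors.

    Returns a molecule table with columns ``sequence`` (40-nt barcode
    pair), ``origin`` (input | switch | error), ``birth_cycle``,
    ``final_copies``, ``class_pair``, ``tag``.  Origins partition the rows;
    input sequences never change content.  Warnings (e.g. the
    ``s0 << 1/N_j`` regime being violated) are recorded in
    ``df.attrs['warnings']``.
    """
    rng = as_rng(rng)
    seqs = [m.barcode_pair for m in pool]
    tags = [m.tag for m in pool]
    classes = [m.class_pair for m in pool]
    counts = np.array([m.copy_number_before_pcr for m in pool], dtype=np.int64)
    origins = ["input"] * len(pool)
    births = [0] * len(pool)
    notes: list[str] = []

    def _n_events(expected: float) -> int:
        if cfg.deterministic_events:
            return int(round(expected))
        return int(rng.poisson(expected))

    for j in range(1, cfg.cycles + 1):
        n_prev = int(counts.sum())
        counts = counts + rng.binomial(counts, cfg.p_amp)
        n_j = int(counts.sum())

        n_err = _n_events(cfg.e_molecule * n_prev) if cfg.e_molecule > 0 else 0
        n_sw = _n_events(cfg.s0 * float(n_j) ** 2) if cfg.s0 > 0 else 0
        if cfg.s0 > 0 and cfg.s0 * n_j > 0.01:
            notes.append(
                f"cycle {j}: s0*N_j = {cfg.s0 * n_j:.3g} violates the s0 << 1/N_j regime"
            )
        if n_err + n_sw == 0:
            continue
        n_existing = counts.size  # parents: molecules present this cycle
        p_parent = counts / counts.sum()
        for _ in range(n_err):
            parent = int(rng.choice(n_existing, p=p_parent))
            seqs.append(_substitute(seqs[parent], rng))
            tags.append(tags[parent])
            classes.append(classes[parent])
            origins.append("error")
            births.append(j)
        for _ in range(n_sw):
            a = int(rng.choice(n_existing, p=p_parent))
            b = int(rng.choice(n_existing, p=p_parent))
            seqs.append(seqs[a][:BARCODE_LEN] + seqs[b][BARCODE_LEN:])
            tags.append(tags[b])  # the tag sits on the second-barcode side
            classes.append((classes[a][0], classes[b][1]))
            origins.append("switch")
            births.append(j)
        if n_err + n_sw > 0:
            counts = np.concatenate([counts, np.ones(n_err + n_sw, dtype=np.int64)])
            # newly born molecules amplify starting from the next cycle

    df = pd.DataFrame(
        {
            "sequence": seqs,
            "origin": origins,
            "birth_cycle": births,
            "final_copies": counts,
            "class_pair": classes,
            "tag": tags,
        }
    )
    df.attrs["warnings"] = notes
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return df


def poisson_sequencing_sample(
    copies, model: SequencingModel, rng
) -> np.ndarray:
    """Read counts per sequence: Poisson(lam * copies)."""
    rng = as_rng(rng)
    copies = np.asarray(copies)
    if (copies < 0).any():
        raise ValueError("copy numbers must be >= 0")
    lam = model.solve_lam(copies)
    return rng.poisson(lam * copies.astype(float)).astype(np.int64)
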