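"""Orthonormal projection kernel for tetranucleotide frequencies.

A contig's 256 raw tetramer frequencies are highly redundant. Three linear
constraints hold (exactly or approximately) for any long double-stranded
sequence:

1. *Reverse-complement symmetry.* Counting k-mers on an assembled contig
   conflates the two strands, so informative features must be invariant
   under the permutation that maps each tetramer to its reverse complement.
2. *Unit sum.* Frequencies sum to one, so the deviation from the uniform
   vector is orthogonal to the all-ones direction.
3. *Trimer continuity.* Every occurrence of a trimer ``t`` away from the
   sequence ends is simultaneously the prefix of one tetramer and the
   suffix of another, hence ``sum_x f(t+x) = sum_x f(x+t)`` for each of the
   64 trimers, up to edge effects.

The kernel is an orthonormal basis of the null space of the stacked
constraint system over the 256-dimensional frequency-deviation vector. Its
dimension is 103, which is the width of the TNF block in the feature table.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

BASES = "ACGT"
N_TETRAMERS = 256
TNF_DIM = 103

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def tetramers() -> list[str]:
    """All 256 tetramers in lexicographic order over the alphabet ACGT.

    This ordering defines the index convention used by raw tetramer count
    vectors throughout the package.
    """
    return ["".join(p) for p in itertools.product(BASES, repeat=4)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def rc_permutation() -> np.ndarray:
    """Index permutation mapping each tetramer to its reverse complement."""
    tet = tetramers()
    index = {t: i for i, t in enumerate(tet)}
    return np.array([index[reverse_complement(t)] for t in tet], dtype=np.intp)


def constraint_matrix() -> np.ndarray:
    """Stacked linear constraints on the 256-dim frequency deviation vector.

    Rows, in order: one ``e_i - e_rc(i)`` row per non-palindromic tetramer
    pair (RC symmetry), the all-ones row (unit sum), and 64 trimer
    prefix/suffix continuity rows.
    """
    tet = tetramers()
    index = {t: i for i, t in enumerate(tet)}
    perm = rc_permutation()
    rows = []
    for i, j in enumerate(perm):
        if i < j:
            row = np.zeros(N_TETRAMERS)
            row[i] = 1.0
            row[j] = -1.0
            rows.append(row)
    rows.append(np.ones(N_TETRAMERS))
    for t in ("".join(p) for p in itertools.product(BASES, repeat=3)):
        row = np.zeros(N_TETRAMERS)
        for b in BASES:
            row[index[t + b]] += 1.0
            row[index[b + t]] -= 1.0
        rows.append(row)
    return np.asarray(rows)


@lru_cache(maxsize=1)
def projection_kernel() -> np.ndarray:
    """The fixed 256 x 103 orthonormal projection matrix.

    Columns form an orthonormal basis (via SVD null-space computation) of
    the subspace satisfying all constraints in :func:`constraint_matrix`.
    The result is deterministic and cached per process.
    """
    kernel = null_space(constraint_matrix())
    kernel.setflags(write=False)
    return kernel
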