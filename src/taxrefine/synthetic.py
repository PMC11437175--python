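"""Synthetic metagenomic communities for testing and benchmarking.

The generator emulates the statistical structure the refiner relies on,
without simulating reads or assembly: each species gets (i) its own base
composition drawn from a Dirichlet, so contigs of the same species share a
tetranucleotide signature, and (ii) its own log-normal abundance profile
across samples, so they also share a depth pattern. Contigs are emitted as
i.i.d. draws from the species composition with lengths uniform in a range,
and per-contig depth adds log-normal noise around the species profile.

``corrupt_annotations`` then emulates an imperfect classifier: a fraction
of contigs lose their annotation entirely, a fraction keep only a prefix
truncated at a random rank, and a fraction get the wrong species — with a
preference for a sibling species in the same genus, mimicking how real
classifiers confuse close relatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import N_RANKS, AnnotationSet, Lineage, TaxTree

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults describe the desk-scale benchmark community: 8 species in
    2 genera under 2 families, 3 samples, 50 contigs per species of
    2–6 kb. ``composition_alpha`` is the Dirichlet concentration for
    per-species base frequencies (smaller = more divergent species);
    ``abundance_sigma`` is the log-scale spread of species abundances
    across samples; ``depth_noise_sigma`` is per-contig log-normal depth
    noise around the species profile.
    """

    n_species: int = 8
    species_per_genus: int = 4
    genera_per_family: int = 1
    n_samples: int = 3
    contigs_per_species: int = 50
    contig_length_range: tuple[int, int] = (2000, 6000)
    composition_alpha: float = 8.0
    abundance_mean_depth: float = 20.0
    abundance_sigma: float = 1.0
    depth_noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.species_per_genus, self.genera_per_family,
               self.n_samples, self.contigs_per_species) < 1:
            raise ValueError("all community counts must be positive")
        if self.contig_length_range[0] < 4 or (
            self.contig_length_range[1] < self.contig_length_range[0]
        ):
            raise ValueError("invalid contig length range")


@dataclass
class Community:
    """A generated community: sequences, depths and true lineages."""

    sequences: list[tuple[str, str]]  # (contig id, sequence)
    depths: pd.DataFrame  # contigname index, one column per sample
    truth: AnnotationSet
    species_lineages: list[tuple[str, ...]]

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.sequences]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write fasta/depth-TSV/truth-TSV in the dialects the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "contigs.fna",
            "depths": outdir / "depths.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for cid, seq in self.sequences:
                fh.write(f">{cid}\n")
                for start in range(0, len(seq), 80):
                    fh.write(seq[start : start + 80] + "\n")
        self.depths.rename_axis("contigname").to_csv(
            paths["depths"], sep="\t", float_format="%.6f"
        )
        self.truth.to_tsv(paths["truth"])
        return paths


def _species_lineage(spec: CommunitySpec, s: int) -> tuple[str, ...]:
    genus = s // spec.species_per_genus
    family = genus // spec.genera_per_family
    return (
        "Bacteria",
        f"Phylum_{family + 1}",
        f"Class_{family + 1}",
        f"Order_{family + 1}",
        f"Family_{family + 1}",
        f"Genus_{genus + 1}",
        f"Species_{s + 1}",
    )


def generate_community(spec: CommunitySpec) -> Community:
    """Generate a community deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lineages: dict[str, Lineage] = {}
    sequences: list[tuple[str, str]] = []
    depth_rows = []
    species_lineages = [_species_lineage(spec, s) for s in range(spec.n_species)]

    lo, hi = spec.contig_length_range
    for s, lineage in enumerate(species_lineages):
        base_freq = rng.dirichlet(np.full(4, spec.composition_alpha))
        log_mean = np.log(spec.abundance_mean_depth)
        species_depth = rng.lognormal(log_mean, spec.abundance_sigma, size=spec.n_samples)
        for c in range(spec.contigs_per_species):
            cid = f"S{s + 1}C{c + 1}"
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(BASES, size=length, p=base_freq))
            sequences.append((cid, seq))
            noise = rng.lognormal(0.0, spec.depth_noise_sigma, size=spec.n_samples)
            depth_rows.append(species_depth * noise)
            lineages[cid] = Lineage(cid, lineage)

    depths = pd.DataFrame(
        np.asarray(depth_rows),
        index=[cid for cid, _ in sequences],
        columns=[f"sample{i + 1}" for i in range(spec.n_samples)],
    )
    return Community(
        sequences=sequences,
        depths=depths,
        truth=AnnotationSet(lineages, source_name="truth"),
        species_lineages=species_lineages,
    )


def corrupt_annotations(
    truth: AnnotationSet,
    error_rate: float = 0.0,
    drop_rate: float = 0.0,
    truncate_rate: float = 0.0,
    seed: int = 0,
    sibling_preference: float = 0.5,
    tree: TaxTree | None = None,
) -> AnnotationSet:
    """Derive an imperfect classifier annotation set from the truth.

    Per contig, one uniform draw decides its fate: dropped (empty
    lineage), truncated at a uniformly random rank above its deepest, or —
    for species-level lineages — relabelled to a different species, which
    with probability ``sibling_preference`` is drawn from the same genus
    when a sibling exists. Rates must sum to at most 1; the remainder keeps
    the truth unchanged. Deterministic per seed; the contig set is
    preserved.
    """
    for name, rate in (("error_rate", error_rate), ("drop_rate", drop_rate),
                       ("truncate_rate", truncate_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if drop_rate + truncate_rate + error_rate > 1.0 + 1e-12:
        raise ValueError("corruption rates must sum to at most 1")
    rng = np.random.default_rng(seed)

    species_pool = sorted(
        {lin.labels for lin in truth.lineages.values() if lin.depth == N_RANKS}
    )
    by_genus: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
    for path in species_pool:
        by_genus.setdefault(path[:-1], []).append(path)

    out: dict[str, Lineage] = {}
    for cid in truth.lineages:  # insertion order: deterministic
        lin = truth.lineages[cid]
        u = rng.random()
        if u < drop_rate:
            out[cid] = Lineage(cid)
        elif u < drop_rate + truncate_rate and lin.depth > 1:
            cut = int(rng.integers(1, lin.depth))
            out[cid] = Lineage(cid, lin.labels[:cut])
        elif u < drop_rate + truncate_rate + error_rate and lin.depth == N_RANKS:
            siblings = [p for p in by_genus.get(lin.labels[:-1], []) if p != lin.labels]
            others = [p for p in species_pool if p != lin.labels]
            if siblings and (rng.random() < sibling_preference or not others):
                choice = siblings[int(rng.integers(len(siblings)))]
            elif others:
                choice = others[int(rng.integers(len(others)))]
            else:
                choice = lin.labels
            out[cid] = Lineage(cid, choice)
        else:
            out[cid] = Lineage(cid, lin.labels)
    return AnnotationSet(out, source_name=f"{truth.source_name}+corrupted")
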