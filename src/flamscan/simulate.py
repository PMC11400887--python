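"""Synthetic genomes with planted cluster and centromere regions.

Generates everything the pipeline consumes — contig sets, strand-resolved
Gypsy TE fragment annotations (plus a Copia decoy family), and truth BED
intervals — with no sequence content, since the model never looks at
nucleotides. The emulated data regime mirrors the biology the model
exploits: flam-like clusters are dense in Gypsy fragments on one strand,
centromere-like regions are dense on both strands, and the background is
sparse.

Fragments are laid down by a non-overlapping walk with exponential gaps
sized so that the realised covered fraction of a region matches the
requested per-base density in expectation. All draws go through a single
seeded generator, so a given spec is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crossval import SpeciesData
from .genome import BinGrid, ContigSet
from .hmm import HMMParams, sample_path
from .labels import Interval, StateTrack, read_bed_intervals
from .te import EmissionTrack, TEFeature, read_te_annotations

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "simulate_genome",
    "simulate_corpus",
    "simulate_from_hmm",
    "write_species_files",
    "write_corpus",
    "read_manifest",
]

GYPSY_LABEL = "Gypsy_LTR_retrotransposon"
DECOY_LABEL = "Copia_LTR_retrotransposon"


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic species genome.

    Defaults describe a compact but realistic regime: a few
    half-to-two-megabase contigs, one planted 100-200 kb cluster with
    strongly one-sided Gypsy content (density 0.5, strand bias 0.95), one
    150-300 kb centromere-like region dense on both strands, and a sparse
    (2%) background. ``seed`` is mandatory; every draw derives from it.
    """

    seed: int
    species_id: str = "sim"
    n_contigs: int = 3
    contig_length_range: tuple[int, int] = (500_000, 2_000_000)
    n_clusters: int = 1
    cluster_length_range: tuple[int, int] = (100_000, 200_000)
    cluster_te_density: float = 0.5
    cluster_strand_bias: float = 0.95
    n_centromeres: int = 1
    centromere_length_range: tuple[int, int] = (150_000, 300_000)
    centromere_te_density: float = 0.5
    background_te_density: float = 0.02
    decoy_te_density: float = 0.02
    fragment_length_range: tuple[int, int] = (300, 3000)

    def __post_init__(self) -> None:
        for name in (
            "cluster_te_density",
            "centromere_te_density",
            "background_te_density",
            "decoy_te_density",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.5 <= self.cluster_strand_bias <= 1:
            raise ValueError("cluster_strand_bias must lie in [0.5, 1]")


def _fill_fragments(
    rng: np.random.Generator,
    contig: str,
    lo: int,
    hi: int,
    density: float,
    frag_range: tuple[int, int],
    strand_of: "callable",
    label: str,
    out: list[TEFeature],
) -> None:
    """Non-overlapping fragment walk targeting a covered fraction of `density`.

    Each gap is proportional to the preceding fragment's length with a
    bounded random multiplier, so the covered/total ratio concentrates
    tightly on `density` even for regions of a few tens of kilobases.
    """
    if density <= 0 or hi - lo < 2:
        return
    gap_factor = (1 - density) / density  # 0 at density 1: back-to-back tiling
    mean_frag = (frag_range[0] + frag_range[1]) / 2
    pos = lo + mean_frag * gap_factor * rng.uniform(0.0, 1.0)
    while pos < hi - 1:
        start = int(pos)
        length = int(rng.integers(frag_range[0], frag_range[1] + 1))
        end = min(start + length, hi)
        if end > start:
            out.append(TEFeature(contig, start, end, strand_of(), label))
        pos = end + (end - start) * gap_factor * rng.uniform(0.5, 1.5)


def _place_regions(
    rng: np.random.Generator,
    contigs: ContigSet,
    n: int,
    length_range: tuple[int, int],
    occupied: dict[str, list[tuple[int, int]]],
) -> list[Interval]:
    """Place `n` non-overlapping regions uniformly across contigs."""
    placed: list[Interval] = []
    for _ in range(n):
        for _attempt in range(500):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            fitting = [(cn, cl) for cn, cl in contigs if cl >= length]
            if not fitting:
                raise ValueError(
                    "could not place all planted regions; the spec is infeasible "
                    "(regions exceed available contig space)"
                )
            cname, clen = fitting[int(rng.integers(len(fitting)))]
            start = int(rng.integers(0, clen - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied.get(cname, [])):
                occupied.setdefault(cname, []).append((start, end))
                placed.append((cname, start, end))
                break
        else:
            raise ValueError(
                "could not place all planted regions; the spec is infeasible "
                "(regions exceed available contig space)"
            )
    return placed


def simulate_genome(spec: SimSpec) -> SpeciesData:
    """Generate one synthetic species from a :class:`SimSpec`.

    Returns contigs, the full (unfiltered) TE feature list including the
    Copia decoy family, and the truth cluster/centromere intervals.
    Cluster fragments fall on the cluster's TE strand with probability
    ``cluster_strand_bias``; centromere and background fragments split
    evenly across strands.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.contig_length_range
    contigs = ContigSet.from_entries(
        (f"{spec.species_id}_contig_{i + 1}", int(rng.integers(lo, hi + 1)))
        for i in range(spec.n_contigs)
    )
    occupied: dict[str, list[tuple[int, int]]] = {}
    clusters = _place_regions(
        rng, contigs, spec.n_clusters, spec.cluster_length_range, occupied
    )
    centromeres = _place_regions(
        rng, contigs, spec.n_centromeres, spec.centromere_length_range, occupied
    )

    features: list[TEFeature] = []
    coin = lambda: "+" if rng.random() < 0.5 else "-"
    for cname, s, e in clusters:
        te_strand = coin()
        other = "-" if te_strand == "+" else "+"
        biased = lambda: te_strand if rng.random() < spec.cluster_strand_bias else other
        _fill_fragments(
            rng, cname, s, e, spec.cluster_te_density,
            spec.fragment_length_range, biased, GYPSY_LABEL, features,
        )
    for cname, s, e in centromeres:
        _fill_fragments(
            rng, cname, s, e, spec.centromere_te_density,
            spec.fragment_length_range, coin, GYPSY_LABEL, features,
        )
    # sparse background Gypsy outside the planted regions
    for cname, clen in contigs:
        regions = sorted(occupied.get(cname, []))
        cursor = 0
        for s, e in regions + [(clen, clen)]:
            _fill_fragments(
                rng, cname, cursor, s, spec.background_te_density,
                spec.fragment_length_range, coin, GYPSY_LABEL, features,
            )
            cursor = e
    # decoy family across the whole genome; removed by the Gypsy filter
    for cname, clen in contigs:
        _fill_fragments(
            rng, cname, 0, clen, spec.decoy_te_density,
            spec.fragment_length_range, coin, DECOY_LABEL, features,
        )

    return SpeciesData(
        species_id=spec.species_id,
        contigs=contigs,
        features=features,
        cluster_intervals=clusters,
        centromere_intervals=centromeres,
    )


def simulate_corpus(
    seed: int,
    n_train: int = 6,
    n_test: int = 2,
    **spec_overrides,
) -> tuple[list[SpeciesData], list[SpeciesData]]:
    """Generate the default corpus: training and held-out test species.

    Per-species seeds are derived deterministically from ``seed``. Extra
    keyword arguments override :class:`SimSpec` fields for every species.
    """
    n = n_train + n_test
    child_seeds = (np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF).tolist()
    species = []
    for i in range(n):
        role = "train" if i < n_train else "test"
        idx = i + 1 if i < n_train else i - n_train + 1
        spec = SimSpec(
            seed=int(child_seeds[i]),
            species_id=f"{role}_{idx:02d}",
            **spec_overrides,
        )
        species.append(simulate_genome(spec))
    return species[:n_train], species[n_train:]


def simulate_from_hmm(
    params: HMMParams, grid: BinGrid, seed: int
) -> tuple[StateTrack, EmissionTrack]:
    """Sample per-contig state and emission tracks directly from a model."""
    pairs = sample_path(params, grid.segment_lengths(), seed)
    states = np.concatenate([s for s, _ in pairs])
    emissions = np.concatenate([e for _, e in pairs])
    threshold = float(params.metadata.get("threshold", 0.0)) or 0.075
    return (
        StateTrack(grid=grid, states=states, provenance="predicted"),
        EmissionTrack(grid=grid, symbols=emissions, threshold=threshold),
    )


# -- corpus file IO ---------------------------------------------------


def write_species_files(sp: SpeciesData, out_dir: str | Path) -> dict[str, Path]:
    """Write one species as chrom.sizes + BED6 TEs + truth BEDs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": out_dir / "chrom.sizes",
        "te": out_dir / "te_annotations.bed",
        "clusters": out_dir / "clusters_truth.bed",
        "centromeres": out_dir / "centromeres_truth.bed",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in sp.contigs:
            fh.write(f"{name}\t{length}\n")
    with open(paths["te"], "w") as fh:
        for f in sp.features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.family_label}\t0\t{f.strand}\n")
    for key, intervals in (
        ("clusters", sp.cluster_intervals),
        ("centromeres", sp.centromere_intervals),
    ):
        with open(paths[key], "w") as fh:
            for contig, s, e in intervals:
                fh.write(f"{contig}\t{s}\t{e}\n")
    return paths


def write_corpus(
    train: list[SpeciesData], test: list[SpeciesData], out_dir: str | Path
) -> Path:
    """Write a corpus directory with a per-species manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("species\trole\tchrom_sizes\tte\tclusters\tcentromeres\n")
        for role, group in (("train", train), ("test", test)):
            for sp in group:
                paths = write_species_files(sp, out_dir / sp.species_id)
                fh.write(
                    f"{sp.species_id}\t{role}\t{paths['chrom_sizes']}\t{paths['te']}\t"
                    f"{paths['clusters']}\t{paths['centromeres']}\n"
                )
    return manifest


def read_manifest(path: str | Path, role: str | None = None) -> list[SpeciesData]:
    """Load species listed in a corpus manifest, optionally by role."""
    from .genome import read_contig_lengths

    path = Path(path)
    species: list[SpeciesData] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if role is not None and f[col["role"]] != role:
                continue
            species.append(
                SpeciesData(
                    species_id=f[col["species"]],
                    contigs=read_contig_lengths(f[col["chrom_sizes"]]),
                    features=read_te_annotations(f[col["te"]]),
                    cluster_intervals=read_bed_intervals(f[col["clusters"]]),
                    centromere_intervals=read_bed_intervals(f[col["centromeres"]]),
                )
            )
    return species
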