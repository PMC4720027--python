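"""Synthetic data generators with ground truth.

Everything the quantification pipeline consumes can be simulated here:

* daily fluorescence images of nuclei confined to circular adhesive
  features on a micropatterned plate, with true per-feature cell counts;
* amplicon sequencing reads carrying insertions/deletions centred at the
  Cas9 cut site, with a per-read ground-truth edit label;
* genotyping-gel band tables for paired-sgRNA deletion clones, with true
  genotype labels.

Ground truth is emitted alongside every dataset as a pandas DataFrame; it
is meant for scoring the analysis stages and is never consumed by them.
All generators are bit-reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import PairedDeletionDesign
from .plates import PlateLayout

__all__ = [
    "CloneSimParams",
    "ReadSimConfig",
    "generate_plate_timelapse",
    "write_plate_images",
    "image_filename",
    "simulate_amplicon_reads",
    "write_fastq",
    "simulate_gel_table",
]


# --------------------------------------------------------------------------
# plate time-lapse
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSimParams:
    """Parameters of the clonal seeding / growth / imaging simulation.

    Seeding is Poisson per feature (limiting dilution at clonal density).
    Growth is a discrete-time branching process evaluated once per day to
    match the daily imaging cadence: each cell first survives with
    probability ``1 - death_prob_per_day`` and then divides with
    probability ``exp(growth_rate_per_day) - 1``, so the expected count
    multiplies by ``exp(r)`` per day (requires ``r <= ln 2``).  With the
    default rate of ln 2 per day (a 24-hour doubling time, typical of
    cultured human pluripotent stem cells) every surviving cell divides
    daily and growth is deterministic.

    Nuclei are rendered as 2-D Gaussian spots clipped to the feature disk
    on a constant background with additive Gaussian read-out noise.
    """

    seeding_density_lambda: float = 1.0
    growth_rate_per_day: float = math.log(2.0)
    death_prob_per_day: float = 0.0
    nucleus_radius_px: float = 4.0
    intensity_mean: float = 12000.0
    intensity_sd: float = 2000.0
    background_level: float = 800.0
    noise_sd: float = 120.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seeding_density_lambda < 0:
            raise ValueError("seeding_density_lambda must be >= 0")
        if not 0.0 <= self.death_prob_per_day <= 1.0:
            raise ValueError("death_prob_per_day must be in [0, 1]")
        if self.growth_rate_per_day > math.log(2.0) + 1e-12:
            raise ValueError(
                "growth_rate_per_day must be <= ln(2): cells divide at most "
                "once per imaging day"
            )
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        for name in ("intensity_mean", "intensity_sd", "background_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def division_prob_per_day(self) -> float:
        return math.exp(self.growth_rate_per_day) - 1.0


def _branching_counts(
    seed_count: int, n_days: int, p_div: float, p_death: float, rng: np.random.Generator
) -> list[int]:
    """Daily counts of a Galton-Watson process; index 0 is the seeded count."""
    counts = [seed_count]
    n = seed_count
    for _ in range(n_days - 1):
        if n == 0:
            counts.append(0)
            continue
        survivors = n - int(rng.binomial(n, p_death)) if p_death > 0 else n
        if p_div >= 1.0:
            dividers = survivors
        elif p_div <= 0.0:
            dividers = 0
        else:
            dividers = int(rng.binomial(survivors, p_div))
        n = survivors + dividers
        counts.append(n)
    return counts


def _place_nuclei(
    n: int, radius_px: float, min_sep: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``n`` centres inside the feature disk, pairwise
    separated by ``min_sep`` pixels (separation is relaxed if the disk
    gets crowded)."""
    centre = size / 2.0
    placed: list[tuple[float, float]] = []
    sep = min_sep
    attempts = 0
    while len(placed) < n:
        r = radius_px * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        x = centre + r * math.cos(theta)
        y = centre + r * math.sin(theta)
        if all((x - px) ** 2 + (y - py) ** 2 >= sep**2 for px, py in placed):
            placed.append((x, y))
            attempts = 0
        else:
            attempts += 1
            if attempts > 200:  # crowded disk: relax separation
                sep *= 0.8
                attempts = 0
    return np.asarray(placed, dtype=float).reshape(n, 2)


def _render_feature(
    centres: np.ndarray,
    amplitudes: np.ndarray,
    layout: PlateLayout,
    params: CloneSimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    size = layout.image_size_px
    img = np.full((size, size), params.background_level, dtype=float)
    yy, xx = np.mgrid[0:size, 0:size]
    centre = size / 2.0
    disk = (xx - centre) ** 2 + (yy - centre) ** 2 <= layout.feature_radius_px**2
    sigma = params.nucleus_radius_px / 2.0
    spots = np.zeros((size, size), dtype=float)
    for (x, y), amp in zip(centres, amplitudes):
        spots += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    img += spots * disk
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_plate_timelapse(
    layout: PlateLayout,
    params: CloneSimParams,
    n_days: int,
    wells: Sequence[int] = (1,),
    seed_counts: Mapping[tuple[int, int, int], int] | None = None,
    growth_rates: Mapping[tuple[int, int, int], float] | None = None,
) -> tuple[dict[tuple[int, int, int, int], np.ndarray], pd.DataFrame]:
    """Simulate a daily-imaged plate.

    Returns ``(images, truth)`` where ``images`` maps
    ``(well, grid_row, grid_col, day)`` (day starting at 0, the seeding
    day) to a 16-bit image, and ``truth`` is a DataFrame with columns
    ``well, grid_row, grid_col, day, true_count`` plus a per-feature
    ``true_rate_per_day`` column.

    ``seed_counts`` / ``growth_rates`` optionally override the Poisson
    seeding draw or the global growth rate per feature, keyed by
    ``(well, grid_row, grid_col)`` — used to build mixed populations of
    clones with distinct proliferation rates.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if layout.image_size_px <= 0:
        raise ValueError("image dimensions must be positive")
    rng = np.random.default_rng(params.rng_seed)
    images: dict[tuple[int, int, int, int], np.ndarray] = {}
    rows = []
    for well in wells:
        for gr, gc in layout.positions():
            key = (well, gr, gc)
            if seed_counts is not None and key in seed_counts:
                n0 = int(seed_counts[key])
            else:
                n0 = int(rng.poisson(params.seeding_density_lambda))
            rate = (
                growth_rates[key]
                if growth_rates is not None and key in growth_rates
                else params.growth_rate_per_day
            )
            p_div = math.exp(rate) - 1.0
            counts = _branching_counts(
                n0, n_days, p_div, params.death_prob_per_day, rng
            )
            for day, n in enumerate(counts):
                centres = _place_nuclei(
                    n,
                    layout.feature_radius_px - params.nucleus_radius_px - 2,
                    2 * params.nucleus_radius_px + 2,
                    layout.image_size_px,
                    rng,
                )
                amps = np.maximum(
                    rng.normal(params.intensity_mean, params.intensity_sd, n),
                    0.25 * params.intensity_mean,
                )
                images[(well, gr, gc, day)] = _render_feature(
                    centres, amps, layout, params, rng
                )
                rows.append((well, gr, gc, day, n, rate))
    truth = pd.DataFrame(
        rows,
        columns=["well", "grid_row", "grid_col", "day", "true_count", "true_rate_per_day"],
    )
    return images, truth


def image_filename(well: int, grid_row: int, grid_col: int, day: int) -> str:
    """Canonical per-feature image filename."""
    return f"well{well}_pos{grid_row:03d}x{grid_col:03d}_day{day}.tif"


def write_plate_images(
    images: Mapping[tuple[int, int, int, int], np.ndarray], directory: str | Path
) -> list[Path]:
    """Write one 16-bit grayscale TIFF per (well, position, day)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (well, gr, gc, day), img in images.items():
        path = directory / image_filename(well, gr, gc, day)
        tifffile.imwrite(path, img)
        paths.append(path)
    return paths


# --------------------------------------------------------------------------
# amplicon reads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the amplicon read simulator.

    Each read is wild type with probability ``1 - edit_fraction``;
    otherwise it carries a single indel: a deletion with probability
    ``p_deletion_given_indel`` (default 0.85, the empirical deletion:
    insertion mixture of Cas9-edited human cells), else an insertion.
    Indel lengths are drawn from ``indel_length_dist`` (mapping length ->
    probability; default uniform over 1..30 nt).  The indel is centred on
    the cut site with signed Gaussian positional jitter.

    Sequencing errors are substitutions only by default, so that every
    indel in the data is attributable to an edit; set
    ``allow_indel_errors`` to add rare 1-nt error indels for robustness
    experiments.
    """

    n_reads: int = 1000
    edit_fraction: float = 0.5
    p_deletion_given_indel: float = 0.85
    indel_length_dist: Mapping[int, float] | None = None
    cut_offset_from_pam: int = 3
    positional_jitter_sd: float = 1.0
    seq_error_rate: float = 0.0
    indel_error_rate: float = 0.001
    allow_indel_errors: bool = False
    read_length: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edit_fraction", "p_deletion_given_indel", "seq_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")

    def length_distribution(self) -> dict[int, float]:
        if self.indel_length_dist is None:
            return {length: 1.0 / 30.0 for length in range(1, 31)}
        dist = {int(k): float(v) for k, v in self.indel_length_dist.items()}
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("indel_length_dist probabilities must sum to 1")
        if any(k < 1 for k in dist):
            raise ValueError("indel lengths must be positive integers")
        return dist


_BASES = np.array(list("ACGT"))


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_amplicon_reads(
    ref,
    config: ReadSimConfig,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate amplicon reads around a Cas9 cut site.

    ``ref`` is an :class:`~clonegrid.indels.AmpliconReference` (anything
    with ``sequence`` and a ``cut_sites`` list will do).  Returns FASTQ
    records (Phred+33, constant Q37) and a ground-truth DataFrame with
    columns ``read_id, label, indel_type, length, position`` where
    ``label`` is ``WT``, ``deletion`` or ``insertion`` and ``position``
    is the reference start of the event.
    """
    sequence = ref.sequence
    cut = ref.cut_sites[0]
    read_length = config.read_length or len(sequence)
    if len(sequence) < read_length:
        raise ValueError("reference length must be >= read_length")
    if not 0 < cut < read_length:
        raise ValueError("cut site must lie strictly inside the read window")

    rng = np.random.default_rng(config.rng_seed)
    dist = config.length_distribution()
    lengths = np.array(sorted(dist))
    probs = np.array([dist[k] for k in lengths])

    records: list[SeqRecord] = []
    rows = []
    for i in range(config.n_reads):
        read_id = f"read{i:06d}"
        edited = rng.random() < config.edit_fraction
        if not edited:
            seq = sequence
            label, itype, length, pos = "WT", "", 0, -1
        else:
            length = int(rng.choice(lengths, p=probs))
            jitter = int(round(rng.normal(0.0, config.positional_jitter_sd)))
            is_del = rng.random() < config.p_deletion_given_indel
            if is_del:
                # deletion spanning the (jittered) cut bond
                start = cut + jitter - length // 2
                start = max(1, min(start, len(sequence) - length - 1))
                seq = sequence[:start] + sequence[start + length :]
                label, itype, pos = "deletion", "del", start
            else:
                pos = max(1, min(cut + jitter, len(sequence) - 1))
                insert = "".join(rng.choice(_BASES, size=length))
                seq = sequence[:pos] + insert + sequence[pos:]
                label, itype = "insertion", "ins"
        seq = _substitute(seq, config.seq_error_rate, rng)
        if config.allow_indel_errors and rng.random() < config.indel_error_rate:
            p = int(rng.integers(1, len(seq) - 1))
            if rng.random() < 0.5:
                seq = seq[:p] + seq[p + 1 :]
            else:
                seq = seq[:p] + "ACGT"[int(rng.integers(4))] + seq[p:]
        seq = seq[:read_length]
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [37] * len(seq)
        records.append(rec)
        rows.append((read_id, label, itype, length if edited else 0, pos))
    truth = pd.DataFrame(
        rows, columns=["read_id", "label", "indel_type", "length", "position"]
    )
    return records, truth


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> Path:
    from Bio import SeqIO

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return path


# --------------------------------------------------------------------------
# genotyping gels
# --------------------------------------------------------------------------

GENOTYPES = ("WT", "monoallelic", "biallelic")


def simulate_gel_table(
    n_clones: int,
    genotype_fractions: Mapping[str, float],
    designs: Sequence[PairedDeletionDesign],
    rng_seed: int = 0,
    band_jitter_sd_bp: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate genotyping-gel band tables for paired-sgRNA clones.

    Each clone draws a genotype from ``genotype_fractions`` (keys among
    ``WT``, ``monoallelic``, ``biallelic``).  A WT allele contributes the
    full-length amplicon band; a deleted allele contributes the edited
    amplicon of a design drawn uniformly at random.  A biallelic clone
    carrying the same deletion on both alleles (homozygous) shows a
    single band.  Returns ``(bands, truth)``: ``bands`` has one row per
    clone with a semicolon-joined ``bands_bp`` column; ``truth`` carries
    the generating genotype labels.
    """
    fractions = dict(genotype_fractions)
    unknown = set(fractions) - set(GENOTYPES)
    if unknown:
        raise ValueError(f"unknown genotype keys: {sorted(unknown)}")
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("genotype fractions must sum to 1")
    needs_designs = any(
        fractions.get(g, 0.0) > 0 for g in ("monoallelic", "biallelic")
    )
    if needs_designs and not designs:
        raise ValueError("non-WT genotype fractions require at least one design")

    rng = np.random.default_rng(rng_seed)
    labels = list(GENOTYPES)
    probs = np.array([fractions.get(g, 0.0) for g in labels])
    wt_bp = designs[0].wt_amplicon_bp if designs else 0

    band_rows, truth_rows = [], []
    for i in range(n_clones):
        clone = f"clone{i:04d}"
        genotype = labels[int(rng.choice(len(labels), p=probs))]
        if genotype == "WT":
            bands = [wt_bp] if designs else []
        elif genotype == "monoallelic":
            d = designs[int(rng.integers(len(designs)))]
            bands = [wt_bp, d.edited_amplicon_bp]
        else:
            pair = rng.integers(len(designs), size=2)
            bands = sorted({designs[int(j)].edited_amplicon_bp for j in pair},
                           reverse=True)
        if band_jitter_sd_bp > 0:
            bands = [
                max(1, int(round(b + rng.normal(0.0, band_jitter_sd_bp))))
                for b in bands
            ]
        band_rows.append((clone, ";".join(str(b) for b in sorted(bands, reverse=True))))
        truth_rows.append((clone, genotype))
    bands_df = pd.DataFrame(band_rows, columns=["clone_id", "bands_bp"])
    truth_df = pd.DataFrame(truth_rows, columns=["clone_id", "genotype"])
    return bands_df, truth_df
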