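"""Synthetic half-sib pedigree genotypes and season/size-structured counts.

The generators emulate the study design the pipeline is built for: two
seasonal spawning lots, each a set of paternal half-sib families made by
crossing three dams to a single sire, and from each (lot, dam) family one
LARGE and one SMALL offspring — 12 fish in total.  Genotypes follow
Mendelian transmission from Hardy-Weinberg parents; expression counts are
negative-binomial with optional season and size log-fold-change effects.

Every source of randomness derives from one integer seed through named
sub-streams, so e.g. adding markers never perturbs the simulated counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CountTable,
    GenotypeTable,
    Lot,
    SampleRecord,
    SimTruth,
    SizeClass,
)

__all__ = ["default_design", "simulate_pedigree", "simulate_counts"]

# fixed spawn keys: one independent bit-generator stream per purpose
_STREAMS = {
    "parents": 1,
    "transmission": 2,
    "missing": 3,
    "abundance": 4,
    "counts": 5,
    "lengths": 6,
    "planted": 7,
    "de_assignment": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def default_design() -> list[SampleRecord]:
    """The 12-fish study design: 2 lots x 3 dams x {LARGE, SMALL},
    one sire per lot."""
    samples = []
    for lot in (Lot.SEPT, Lot.DEC):
        sire = f"{lot.value}_SIRE"
        for d in range(1, 4):
            dam = f"{lot.value}_D{d}"
            for size, tag in ((SizeClass.LARGE, "L"), (SizeClass.SMALL, "S")):
                samples.append(
                    SampleRecord(
                        sample_id=f"{lot.value}_{tag}{d}",
                        lot=lot,
                        size_class=size,
                        dam_id=dam,
                        sire_id=sire,
                    )
                )
    return samples


def _transmit(rng: np.random.Generator, dosages: np.ndarray) -> np.ndarray:
    """Sample one transmitted allele (0/1) per marker from a parent's dosage:
    homozygotes transmit their allele, heterozygotes a fair coin."""
    het = dosages == 1
    allele = (dosages // 2).astype(np.int64)  # 0 -> 0, 2 -> 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()))
    return allele


def simulate_pedigree(
    n_markers: int = 2000,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    n_planted: int = 0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, list[SampleRecord], SimTruth]:
    """Simulate biallelic genotypes for 8 parents and 12 half-sib offspring.

    Parents are drawn from Hardy-Weinberg equilibrium at a per-marker
    alternate-allele frequency uniform on [maf_low, maf_high].  Each
    offspring receives one allele from its dam and one from its lot's sire,
    sampled uniformly from the parent's two alleles.

    ``n_planted`` markers are made perfectly confounded with size class:
    both sires are heterozygous, all dams homozygous reference, and sire
    transmission is forced so that within each lot every SMALL fish carries
    dosage 0 and every LARGE fish dosage 1 — the within-lot dissimilarity
    index is exactly 1 at these markers when no data are missing.

    Missing values (NaN) are inserted independently per cell at
    ``missing_rate``, in offspring only.

    Returns the full genotype table (parents first, then offspring), the 12
    offspring sample records, and a :class:`SimTruth` naming the planted
    markers.  Downstream analyses consume the offspring rows only, mirroring
    a study in which parental genotypes are unknown.
    """
    if n_planted < 0 or n_markers < n_planted:
        raise ValueError("require n_markers >= n_planted >= 0")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")

    samples = default_design()
    marker_ids = [f"snp{i + 1:05d}" for i in range(n_markers)]
    parent_ids = [f"{lot.value}_{p}" for lot in (Lot.SEPT, Lot.DEC) for p in ("SIRE", "D1", "D2", "D3")]

    rng_par = _rng(seed, "parents")
    freqs = rng_par.uniform(maf_low, maf_high, size=n_markers)
    parent_dos = rng_par.binomial(2, freqs, size=(len(parent_ids), n_markers)).astype(float)

    planted_idx = np.sort(_rng(seed, "planted").choice(n_markers, size=n_planted, replace=False))
    sire_rows = {f"{lot.value}_SIRE": parent_ids.index(f"{lot.value}_SIRE") for lot in Lot}
    for pid, row in enumerate(parent_ids):
        if pid in sire_rows.values():
            parent_dos[pid, planted_idx] = 1.0  # sires heterozygous
        else:
            parent_dos[pid, planted_idx] = 0.0  # dams homozygous reference

    rng_tx = _rng(seed, "transmission")
    off_rows = []
    for s in samples:
        dam_row = parent_dos[parent_ids.index(s.dam_id)]
        sire_row = parent_dos[parent_ids.index(s.sire_id)]
        dam_allele = _transmit(rng_tx, dam_row.astype(np.int64))
        sire_allele = _transmit(rng_tx, sire_row.astype(np.int64))
        # forced sire transmission at planted markers: LARGE gets the
        # alternate allele, SMALL the reference allele
        sire_allele[planted_idx] = 1 if s.size_class is SizeClass.LARGE else 0
        off_rows.append((dam_allele + sire_allele).astype(float))
    offspring_dos = np.vstack(off_rows)

    if missing_rate > 0:
        mask = _rng(seed, "missing").random(offspring_dos.shape) < missing_rate
        offspring_dos[mask] = np.nan

    dosages = pd.DataFrame(
        np.vstack([parent_dos, offspring_dos]),
        index=parent_ids + [s.sample_id for s in samples],
        columns=marker_ids,
    )
    truth = SimTruth(
        seed=seed,
        parameters={
            "n_markers": n_markers,
            "maf_low": maf_low,
            "maf_high": maf_high,
            "n_planted": n_planted,
            "missing_rate": missing_rate,
        },
        planted_marker_ids=[marker_ids[i] for i in planted_idx],
    )
    return GenotypeTable(dosages), samples, truth


def simulate_counts(
    n_contigs: int = 5000,
    frac_season_de: float = 0.1,
    frac_size_de: float = 0.05,
    log2fc: float = 1.5,
    dispersion: float = 0.29**2,
    library_sizes: Sequence[int] | None = None,
    length_low: int = 200,
    length_high: int = 4000,
    seed: int = 0,
    samples: Sequence[SampleRecord] | None = None,
) -> tuple[CountTable, SimTruth]:
    """Simulate a negative-binomial contig x fish count table.

    The mean for contig g in fish i is ``library_size_i * rho_g * 2**(s *
    log2fc * x_i)`` where rho_g is the contig's relative abundance
    (log-normal, normalised to sum to one), s is the contig's random effect
    sign and x_i = +1/2 or -1/2 encodes the fish's level of the contig's
    factor (lot for season-DE contigs, size class for size-DE contigs), so
    group means differ by a full ``2**log2fc``.  Counts are drawn with
    variance mean + dispersion * mean**2; the default dispersion 0.29**2
    corresponds to a biological coefficient of variation of 0.29, a typical
    value for sibling fish.  Contig lengths are uniform on
    [length_low, length_high].
    """
    if not (0 <= frac_season_de <= 1 and 0 <= frac_size_de <= 1):
        raise ValueError("DE fractions must lie in [0, 1]")
    if frac_season_de + frac_size_de > 1:
        raise ValueError("frac_season_de + frac_size_de must not exceed 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if log2fc < 0:
        raise ValueError("log2fc must be non-negative")
    if samples is None:
        samples = default_design()
    if library_sizes is None:
        library_sizes = [2_000_000] * len(samples)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if len(library_sizes) != len(samples):
        raise ValueError("library_sizes length must match the number of samples")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if length_low < 1 or length_high < length_low:
        raise ValueError("require 1 <= length_low <= length_high")

    contig_ids = [f"contig{i + 1:06d}" for i in range(n_contigs)]

    rng_ab = _rng(seed, "abundance")
    rho = np.exp(rng_ab.normal(0.0, 1.5, size=n_contigs))
    rho /= rho.sum()

    n_season = int(round(frac_season_de * n_contigs))
    n_size = int(round(frac_size_de * n_contigs))
    rng_de = _rng(seed, "de_assignment")
    de_idx = rng_de.choice(n_contigs, size=n_season + n_size, replace=False)
    season_idx, size_idx = de_idx[:n_season], de_idx[n_season:]
    signs = rng_de.choice([-1.0, 1.0], size=n_season + n_size)

    # per-fish half coding of each factor
    x_season = np.array([0.5 if s.lot is Lot.SEPT else -0.5 for s in samples])
    x_size = np.array([0.5 if s.size_class is SizeClass.LARGE else -0.5 for s in samples])

    log2_effect = np.zeros((n_contigs, len(samples)))
    log2_effect[season_idx] = signs[:n_season, None] * log2fc * x_season[None, :]
    log2_effect[size_idx] = signs[n_season:, None] * log2fc * x_size[None, :]

    mean = library_sizes[None, :] * rho[:, None] * np.exp2(log2_effect)

    rng_counts = _rng(seed, "counts")
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng_counts.negative_binomial(r, p)

    lengths = _rng(seed, "lengths").integers(length_low, length_high + 1, size=n_contigs)

    table = CountTable(
        pd.DataFrame(counts, index=contig_ids, columns=[s.sample_id for s in samples]),
        pd.Series(lengths, index=contig_ids, name="length_bp"),
    )
    de_list = [(contig_ids[i], "SEASON", float(sg * log2fc)) for i, sg in zip(season_idx, signs[:n_season])]
    de_list += [(contig_ids[i], "SIZE", float(sg * log2fc)) for i, sg in zip(size_idx, signs[n_season:])]
    truth = SimTruth(
        seed=seed,
        parameters={
            "n_contigs": n_contigs,
            "frac_season_de": frac_season_de,
            "frac_size_de": frac_size_de,
            "log2fc": log2fc,
            "dispersion": dispersion,
            "library_sizes": [float(x) for x in library_sizes],
            "length_low": length_low,
            "length_high": length_high,
        },
        de_contig_ids=de_list,
    )
    return table, truth
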