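"""Seeded synthetic-data generator emulating the 14-plot community design.

The generator reproduces the statistical structure the analysis assumes so
every stage can be exercised without field data: a gallery-forest community
of ~14 census plots holding 4-9 tree species each (a focal conifer present
everywhere plus associates), per-species genotype samples of realistic
size, and a few hundred dominant binary loci per species with island-model
background differentiation.  Optionally a minority of loci is planted as
diversifying outliers (per-plot allele-frequency gradients) and/or coupled
to plot-level species diversity through a monotone link, giving known
truth for recovery experiments.

Dominant masking is modelled explicitly: plot allele frequencies are drawn
at the allele level, band phenotypes at the individual level through
phi = q^2 + F_IS q (1 - q), and the truth record keeps both conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import hill_number
from .io import (
    AbundanceTable,
    BinaryMarkerMatrix,
    write_abundance_table,
    write_census,
    write_marker_matrix,
)

__all__ = [
    "SimDesign",
    "gen_community",
    "gen_markers",
    "simulate_dataset",
    "write_dataset",
    "realized_background_fst",
]

_POOL = (
    "Picea",
    "Pinus",
    "Pseudotsuga",
    "Populus",
    "Quercus",
    "Abies",
    "Prunus",
    "Juniperus",
    "Cupressus",
)

#: Per-plot genotype sample-size ranges of the four genotyped species and
#: the number of plots each was sampled in (the community's study design).
_SAMPLE_RANGES = {
    "Picea": (17, 53),
    "Pinus": (3, 17),
    "Pseudotsuga": (10, 11),
    "Populus": (8, 13),
}
_SPECIES_PLOT_COUNTS = {"Picea": 14, "Pinus": 12, "Pseudotsuga": 6, "Populus": 7}


@dataclass
class SimDesign:
    """Parameters of one synthetic community + marker dataset."""

    seed: int
    n_plots: int = 14
    species_pool: tuple[str, ...] = _POOL
    focal_species: str = "Picea"
    richness_range: tuple[int, int] = (4, 9)
    trees_per_plot: tuple[int, int] = (50, 250)
    adult_fraction: float = 0.6
    sample_size_ranges: dict = field(default_factory=lambda: dict(_SAMPLE_RANGES))
    species_plot_counts: dict = field(default_factory=lambda: dict(_SPECIES_PLOT_COUNTS))
    n_loci: int = 240
    background_fst: float = 0.05
    fis: float = 0.1
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    #: planted diversifying loci: (locus_index, q_low, q_high) gradients
    outlier_loci: tuple = ()
    #: number of trailing loci coupled to plot species diversity
    n_coupled_loci: int = 0
    coupling: float = 0.0
    coupled_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.richness_range
        if not 1 <= lo <= hi <= len(self.species_pool):
            raise ValueError(
                f"richness range {self.richness_range} incompatible with a pool of "
                f"{len(self.species_pool)} species"
            )
        if self.focal_species not in self.species_pool:
            raise ValueError("focal species must be in the species pool")
        if not 0.0 < self.background_fst < 1.0:
            raise ValueError("background_fst must lie in (0, 1)")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.n_coupled_loci + len(self.outlier_loci) > self.n_loci:
            raise ValueError("more planted loci than loci")
        for idx, lo_q, hi_q in self.outlier_loci:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"outlier locus index {idx} out of range")
            if not 0.0 < lo_q < hi_q < 1.0:
                raise ValueError("outlier frequency range must be inside (0, 1)")

    @property
    def plot_labels(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_plots)]

    @property
    def locus_ids(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.n_loci)]


def _rng_for(design: SimDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((design.seed, stream)))


def gen_community(
    design: SimDesign, rng: np.random.Generator | None = None
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate the plot x species abundance table and the adult census.

    Per plot: species richness uniform on the configured range, the focal
    species always present, and stem counts from a Dirichlet-multinomial
    with every selected species guaranteed at least one stem.  The census
    N (adult stems) thins each count binomially.
    """
    rng = rng if rng is not None else _rng_for(design, 0)
    pool = list(design.species_pool)
    associates = [s for s in pool if s != design.focal_species]
    counts = pd.DataFrame(
        0, index=design.plot_labels, columns=pool, dtype=int
    )
    for plot in design.plot_labels:
        r = int(rng.integers(design.richness_range[0], design.richness_range[1] + 1))
        chosen = [design.focal_species] + list(
            rng.choice(associates, size=r - 1, replace=False)
        )
        total = int(rng.integers(design.trees_per_plot[0], design.trees_per_plot[1] + 1))
        total = max(total, r)
        weights = rng.dirichlet(np.full(r, 1.2))
        extra = rng.multinomial(total - r, weights)
        for sp, c in zip(chosen, extra):
            counts.loc[plot, sp] = int(c) + 1
    present = counts.columns[(counts.sum(axis=0) > 0)]
    table = AbundanceTable(counts[present])
    census = (
        table.counts.stack().rename("stems").reset_index()
    )
    census.columns = ["plot", "species", "stems"]
    census = census[census["stems"] > 0].reset_index(drop=True)
    census["N"] = rng.binomial(census["stems"], design.adult_fraction)
    census = census.drop(columns="stems")
    return table, census


def _solve_allele_freq(phi: np.ndarray, fis: float) -> np.ndarray:
    """Recessive allele frequency q with q^2 + fis q (1-q) = phi."""
    if fis >= 1.0:
        return np.clip(phi, 1e-4, 1 - 1e-4)
    a = 1.0 - fis
    q = (-fis + np.sqrt(fis**2 + 4.0 * a * phi)) / (2.0 * a)
    return np.clip(q, 1e-4, 1.0 - 1e-4)


def _species_plots(
    design: SimDesign, community: AbundanceTable, species: str
) -> list[str]:
    if species == design.focal_species:
        return list(community.plots)
    counts = community.counts.get(species)
    if counts is None or (counts > 0).sum() < 2:
        raise ValueError(f"species {species!r} occurs in fewer than two plots")
    present = counts[counts > 0].sort_values(ascending=False)
    limit = design.species_plot_counts.get(species, len(present))
    keep = sorted(present.index[: min(limit, len(present))])
    return [str(p) for p in keep]


def gen_markers(
    design: SimDesign,
    community: AbundanceTable,
    species: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BinaryMarkerMatrix, dict]:
    """Generate a binary marker matrix for one genotyped species.

    Neutral loci follow an island model: ancestral recessive-allele
    frequencies uniform on the configured range, plot frequencies beta
    with concentration (1 - F_ST)/F_ST.  Planted outlier loci get a linear
    per-plot allele-frequency gradient; coupled loci make the recessive
    allele frequency — and with it the band-absence (recessive phenotype)
    frequency, which is monotone in the allele frequency — a monotone
    function of the plot's effective species number (order-2 Hill number)
    mixed with uniform noise by the coupling weight.  Band phenotypes are Bernoulli draws of the
    band-absence probability q^2 + F_IS q (1 - q).

    Returns the matrix plus a truth record (allele and phenotype
    frequencies, planted locus ids, sample sizes, the seed).
    """
    species = species or design.focal_species
    # stable per-species stream (never Python's randomised hash())
    rng = rng if rng is not None else _rng_for(design, sum(species.encode()) % 1009 + 1)
    plots = _species_plots(design, community, species)
    J, I = len(plots), design.n_loci
    lo_n, hi_n = design.sample_size_ranges.get(species, (10, 20))
    sizes = rng.integers(lo_n, hi_n + 1, size=J)

    theta = (1.0 - design.background_fst) / design.background_fst
    ancestral = rng.uniform(*design.ancestral_range, size=I)
    q = rng.beta(ancestral[:, None] * theta, (1.0 - ancestral[:, None]) * theta,
                 size=(I, J))
    q = np.clip(q, 1e-4, 1.0 - 1e-4)

    outlier_ids = []
    for idx, q_lo, q_hi in design.outlier_loci:
        q[idx] = np.linspace(q_lo, q_hi, J)
        outlier_ids.append(design.locus_ids[idx])

    coupled_ids = []
    if design.n_coupled_loci > 0:
        nu2 = np.array([hill_number(community.frequencies(p), 2.0) for p in plots])
        # rank-based monotone map: evenly spreads the planted frequencies
        # over the range whatever the spacing of the diversity values,
        # so the planted differentiation does not collapse when plots
        # happen to have similar diversity
        ranks = rankdata(nu2, method="average") - 1.0
        scaled = ranks / max(J - 1, 1)
        f_lo, f_hi = design.coupled_freq_range
        target = f_lo + (f_hi - f_lo) * scaled
        # The monotone link is planted on the recessive-ALLELE frequency; the
        # recessive phenotype frequency q^2 + F_IS q (1-q) is monotone in q,
        # so the band-absence frequency inherits the link, while the
        # allele-level differentiation stays strong enough for the scan to
        # see (planting the phenotype directly would compress the low end
        # of the allele range through the square root of dominance masking).
        # the "noise" component is the locus' own neutral island-model draw,
        # so coupling 0 degenerates exactly to the neutral background model
        for k in range(design.n_coupled_loci):
            idx = I - design.n_coupled_loci + k
            q[idx] = np.clip(
                design.coupling * target + (1.0 - design.coupling) * q[idx],
                1e-4,
                1.0 - 1e-4,
            )
            coupled_ids.append(design.locus_ids[idx])

    absence_prob = q**2 + design.fis * q * (1.0 - q)

    rows_meta, rows_calls = [], []
    for j, plot in enumerate(plots):
        n = int(sizes[j])
        absent = rng.random((n, I)) < absence_prob[:, j][None, :]
        calls = 1.0 - absent.astype(float)
        if design.missing_rate > 0:
            mask = rng.random((n, I)) < design.missing_rate
            calls[mask] = np.nan
        for k in range(n):
            rows_meta.append((f"{species}_{plot}_{k + 1:03d}", species, plot))
            rows_calls.append(calls[k])
    meta = pd.DataFrame(rows_meta, columns=["individual_id", "species", "plot"])
    calls = pd.DataFrame(np.array(rows_calls), columns=design.locus_ids)
    matrix = BinaryMarkerMatrix(meta, calls)
    truth = {
        "seed": design.seed,
        "species": species,
        "plots": plots,
        "sample_sizes": sizes.tolist(),
        "ancestral_allele_freq": ancestral.tolist(),
        "plot_allele_freq": q.tolist(),
        "plot_absence_prob": absence_prob.tolist(),
        "outlier_loci": outlier_ids,
        "coupled_loci": coupled_ids,
        "coupling": design.coupling,
        "fis": design.fis,
        "background_fst": design.background_fst,
    }
    return matrix, truth


def simulate_dataset(design: SimDesign, species: list[str] | None = None) -> dict:
    """Community, census and marker matrices for the requested species.

    Fully deterministic under ``design.seed``: each component draws from
    its own child stream of the design seed.
    """
    community, census = gen_community(design)
    if species is None:
        species = [design.focal_species]
    markers, truths = {}, {}
    for i, sp in enumerate(species):
        rng = _rng_for(design, 100 + i)
        markers[sp], truths[sp] = gen_markers(design, community, sp, rng)
    return {
        "design": design,
        "community": community,
        "census": census,
        "markers": markers,
        "truth": truths,
    }


def write_dataset(bundle: dict, out_dir: str | Path) -> None:
    """Write a simulated bundle in the package's TSV formats plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_abundance_table(bundle["community"], out / "community.tsv")
    write_census(bundle["census"], out / "census.tsv")
    for sp, matrix in bundle["markers"].items():
        write_marker_matrix(matrix, out / f"markers_{sp}.tsv")
    manifest = {"design": asdict(bundle["design"]), "truth": bundle["truth"]}
    (out / "truth.json").write_text(json.dumps(manifest, indent=2, default=list))


def realized_background_fst(truth: dict) -> float:
    """Moment estimate of background F_ST from the true plot allele freqs.

    Mean over non-planted loci of Var_j(q_ij) / (q_bar (1 - q_bar)); under
    the island model the expectation equals the nominal F_ST.
    """
    q = np.asarray(truth["plot_allele_freq"], dtype=float)
    planted = set(truth["outlier_loci"]) | set(truth["coupled_loci"])
    if planted:
        locus_ids = [f"L{i + 1:03d}" for i in range(q.shape[0])]
        keep = [i for i, lid in enumerate(locus_ids) if lid not in planted]
        q = q[keep]
    qbar = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    return float(np.mean(var / (qbar * (1.0 - qbar))))
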