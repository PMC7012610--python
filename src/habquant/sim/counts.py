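"""Synthetic UMI count matrices with planted cell types, an additive
immediate-early-gene (activity-dependent gene, ADG) program, and doublets.

The generative model, per cell:

1. a cell type is drawn from the configured proportions;
2. per-gene expected expression is a gamma-distributed baseline, multiplied
   by the type's fold-change on its marker genes;
3. the expectation is split between mitochondrial and nuclear genes by a
   beta-distributed mitochondrial load, and scaled so the total expected
   UMI count equals a lognormal library size;
4. ADG-active cells receive additional *additive* expected counts on the
   ADG genes (immediate-early-gene induction rides on top of the identity
   program rather than scaling it);
5. doublets are sums of two cells' expected profiles, drawn before
   sampling (co-encapsulation of two cells in one droplet);
6. observed counts are Poisson, or negative binomial via a gamma-Poisson
   mixture with inverse-dispersion ``theta`` (Poisson is the
   ``theta -> inf`` limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..containers import CountMatrix

#: Immediate-early genes scored as the ADG module.
ADG_GENES = ("Fos", "Fosb", "Egr1", "Junb", "Nr4a1", "Dusp18", "Jun", "Jund")


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class CellTypeSpec:
    """One planted cell type.

    ``marker_genes`` may be an explicit list of gene names or an integer
    number of auto-named markers (``<name>-mk<j>``); markers are exclusive
    to their type and up-regulated by ``marker_effect`` fold.
    """

    name: str
    proportion: float
    marker_genes: int | list[str] = 0
    marker_effect: float = 1.0


@dataclass
class AdgProgram:
    """Additive activity-dependent-gene program.

    ``additive_mean`` expected counts are added to every listed gene in
    each ADG-active cell; activity is Bernoulli(``active_fraction``) within
    the affected types (all types when ``affected_types`` is None).
    """

    genes: tuple[str, ...] = ADG_GENES
    additive_mean: float = 8.0
    active_fraction: float = 0.35
    affected_types: list[str] | None = None


@dataclass
class CountSimConfig:
    n_genes: int = 1000
    n_cells: int = 1000
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [CellTypeSpec("typeA", 1.0)]
    )
    library_size_params: tuple[float, float] = (np.log(2500.0), 0.4)
    gene_mean_params: tuple[float, float] = (0.5, 2.0)
    mito_gene_fraction: float = 0.02
    mito_load_params: tuple[float, float] = (2.0, 38.0)
    adg_program: AdgProgram | None = None
    doublet_rate: float = 0.0
    dispersion: float | str = "poisson"
    n_animals: int = 1
    seed: int = 0

    def validate(self) -> None:
        props = [t.proportion for t in self.cell_types]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(f"type proportions sum to {sum(props)}, not 1")
        if any(p < 0 for p in props):
            raise ConfigurationError("negative type proportion")
        for frac, name in [
            (self.mito_gene_fraction, "mito_gene_fraction"),
            (self.doublet_rate, "doublet_rate"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name}={frac} outside [0, 1]")
        if self.adg_program is not None and not (
            0.0 <= self.adg_program.active_fraction <= 1.0
        ):
            raise ConfigurationError("adg active_fraction outside [0, 1]")
        if self.n_genes < self._n_reserved_genes():
            raise ConfigurationError(
                f"n_genes={self.n_genes} smaller than the "
                f"{self._n_reserved_genes()} named genes required"
            )
        if self.dispersion != "poisson" and not (
            isinstance(self.dispersion, (int, float)) and self.dispersion > 0
        ):
            raise ConfigurationError("dispersion must be 'poisson' or a positive number")

    def _n_reserved_genes(self) -> int:
        n = int(round(self.mito_gene_fraction * self.n_genes))
        for t in self.cell_types:
            n += (
                t.marker_genes
                if isinstance(t.marker_genes, int)
                else len(t.marker_genes)
            )
        if self.adg_program is not None:
            n += len(self.adg_program.genes)
        return n


@dataclass
class CountGroundTruth:
    """Planted truth for one generated count matrix."""

    type_labels: np.ndarray  # primary type per cell
    doublet: np.ndarray  # bool per cell
    doublet_partner: np.ndarray  # secondary type name or "" per cell
    adg_active: np.ndarray  # bool per cell
    library_sizes: np.ndarray  # expected total UMIs per cell
    marker_genes: dict  # type name -> list of marker gene names
    gene_baseline: np.ndarray | None = None  # gamma baseline weights per gene


def _gene_names(config: CountSimConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build the gene universe: mito genes, ADG genes, markers, filler."""
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    names: list[str] = [f"mt-Nd{i + 1}" for i in range(n_mito)]
    if config.adg_program is not None:
        names.extend(config.adg_program.genes)
    markers: dict[str, list[str]] = {}
    for t in config.cell_types:
        if isinstance(t.marker_genes, int):
            mk = [f"{t.name}-mk{j + 1}" for j in range(t.marker_genes)]
        else:
            mk = list(t.marker_genes)
        markers[t.name] = mk
        names.extend(mk)
    n_filler = config.n_genes - len(names)
    names.extend(f"Gene{i + 1:05d}" for i in range(n_filler))
    gene_arr = np.array(names, dtype=object)
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_mito[:n_mito] = True
    return gene_arr, is_mito, markers


def generate_counts(config: CountSimConfig) -> tuple[CountMatrix, CountGroundTruth]:
    """Draw a genes × cells UMI matrix and its ground truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, is_mito, markers = _gene_names(config)
    n_genes, n_cells = config.n_genes, config.n_cells

    if n_cells == 0:
        empty = CountMatrix(
            X=sp.csr_matrix((n_genes, 0), dtype=np.int64),
            genes=genes,
            barcodes=np.array([], dtype=object),
        )
        truth = CountGroundTruth(
            type_labels=np.array([], dtype=object),
            doublet=np.array([], dtype=bool),
            doublet_partner=np.array([], dtype=object),
            adg_active=np.array([], dtype=bool),
            library_sizes=np.array([], dtype=float),
            marker_genes=markers,
        )
        return empty, truth

    shape, scale = config.gene_mean_params
    baseline = rng.gamma(shape, scale, size=n_genes) + 1e-6

    type_names = [t.name for t in config.cell_types]
    props = np.array([t.proportion for t in config.cell_types])
    # per-type relative expression profile (baseline x marker fold-change)
    profiles = np.tile(baseline, (len(type_names), 1))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for ti, t in enumerate(config.cell_types):
        mk_idx = [gene_idx[m] for m in markers[t.name]]
        profiles[ti, mk_idx] *= t.marker_effect

    type_of_cell = rng.choice(len(type_names), size=n_cells, p=props / props.sum())
    mu, sigma = config.library_size_params
    lib = rng.lognormal(mu, sigma, size=n_cells)
    a, b = config.mito_load_params
    mito_load = rng.beta(a, b, size=n_cells) if is_mito.any() else np.zeros(n_cells)

    adg_idx = np.array(
        [gene_idx[g] for g in config.adg_program.genes], dtype=int
    ) if config.adg_program is not None else np.array([], dtype=int)
    if config.adg_program is not None:
        affected = config.adg_program.affected_types
        eligible = (
            np.ones(n_cells, dtype=bool)
            if affected is None
            else np.isin(np.array(type_names, dtype=object)[type_of_cell], affected)
        )
        adg_active = eligible & (
            rng.random(n_cells) < config.adg_program.active_fraction
        )
    else:
        adg_active = np.zeros(n_cells, dtype=bool)

    def expected_profile(ti: int, L: float, f_mito: float) -> np.ndarray:
        w = profiles[ti].copy()
        e = np.zeros(n_genes)
        nm = ~is_mito
        e[nm] = w[nm] / w[nm].sum() * (1.0 - f_mito) * L
        if is_mito.any():
            e[is_mito] = w[is_mito] / w[is_mito].sum() * f_mito * L
        return e

    doublet = rng.random(n_cells) < config.doublet_rate
    partner_type = rng.choice(len(type_names), size=n_cells, p=props / props.sum())
    partner_lib = rng.lognormal(mu, sigma, size=n_cells)
    partner_mito = rng.beta(a, b, size=n_cells) if is_mito.any() else np.zeros(n_cells)

    E = np.empty((n_genes, n_cells))
    for c in range(n_cells):
        e = expected_profile(type_of_cell[c], lib[c], mito_load[c])
        if doublet[c]:
            e = e + expected_profile(partner_type[c], partner_lib[c], partner_mito[c])
        if adg_active[c]:
            e[adg_idx] += config.adg_program.additive_mean
        E[:, c] = e

    if config.dispersion == "poisson":
        counts = rng.poisson(E)
    else:
        theta = float(config.dispersion)
        lam = rng.gamma(theta, E / theta)
        counts = rng.poisson(lam)

    barcodes = np.array([f"cell{i + 1:05d}" for i in range(n_cells)], dtype=object)
    obs = pd.DataFrame(
        {
            "animal": [f"A{(i % config.n_animals) + 1}" for i in range(n_cells)],
            "hemisphere": rng.choice(["L", "R"], size=n_cells),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(
        X=sp.csr_matrix(counts.astype(np.int64)),
        genes=genes,
        barcodes=barcodes,
        obs=obs,
    )
    names_arr = np.array(type_names, dtype=object)
    truth = CountGroundTruth(
        type_labels=names_arr[type_of_cell],
        doublet=doublet,
        doublet_partner=np.where(doublet, names_arr[partner_type], ""),
        adg_active=adg_active,
        library_sizes=lib + np.where(doublet, partner_lib, 0.0),
        marker_genes=markers,
        gene_baseline=baseline,
    )
    return cm, truth
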