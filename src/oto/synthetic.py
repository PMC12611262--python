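"""Synthetic multi-cell-type Hi-C and expression data with planted truth.

The generator emulates the statistical structure a compartment-level
organotropism analysis relies on:

* per-chromosome contact matrices with a checkerboard A/B compartment
  pattern on top of power-law distance decay, observed at finite sequencing
  depth (Poisson counts);
* a panel of cell types sharing one lineage: a primary-organ epithelium,
  localized and metastatic cancer derivatives, plus a secondary-organ
  (and optionally a decoy-organ) epithelium with its own localized cancers;
* planted organ-permissive switches: at bins where the two organs' normal
  epithelia disagree, metastatic lines flip toward the secondary organ's
  state at a controlled rate (localized lines at a lower rate);
* a planted epithelial->mesenchymal gradient: each cancer line carries an
  ``emt_parameter`` in [0, 1], and a designated set of "EMT bins" flips
  state once the parameter crosses a per-bin threshold (monotone tilt);
* expression tables whose differential genes live in bins that are A in
  every cell type, while compartment-switching bins carry expression-flat
  genes — transcription and compartment signatures are decoupled by design.

Every planted event is recorded, so downstream estimates can be compared
with truth. All randomness flows from ``config.seed`` through named
sub-streams (one per cell type / per purpose), making panels reproducible
and individual pieces independently re-drawable.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ContactMatrix, StateTrack
from .errors import ConfigError
from .genome import BinIndex, GeneAnnotation, GeneSetCollection, make_bins

__all__ = [
    "SimulationConfig",
    "CellType",
    "CellTypePanel",
    "simulate_panel",
    "simulate_contact_matrix",
    "expected_contact_matrix",
    "simulate_genes",
    "simulate_expression",
    "concat_panels",
]

# planted per-bin classes, relative to one (normal, cancer) pair
PLANT_STABLE = "stable"
PLANT_RANDOM = "random_flip"
PLANT_SHARED = "shared_flip"
PLANT_EMT_FLIP = "emt_flip"
PLANT_EMT_STABLE = "emt_stable"
PLANT_PERMISSIVE_FLIP = "permissive_flip"
PLANT_PERMISSIVE_RETAINED = "permissive_retained"
PLANT_DECOY_DIVERGENT = "decoy_divergent"


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Named random sub-stream: deterministic function of (seed, tags)."""
    entropy = [int(seed)] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system.

    Contact-map parameters: contacts between bins i and j are Poisson with
    mean ``C * (|i-j|+1)**-decay_exponent * (1 +/- checkerboard_strength)``
    (+ for same compartment, - for different), scaled so the expected total
    over unordered bin pairs equals ``depth``.
    """

    n_bins: int = 400
    bin_size: int = 250_000
    compartment_block_length: float = 8.0  # mean bins per A/B block (geometric)
    decay_exponent: float = 1.0
    checkerboard_strength: float = 0.3
    depth: float = 1e6
    switch_rate_cancer: float = 0.05
    shared_switch_fraction: float = 0.5  # share of cancer switches that are clonal
    permissive_switch_rate_metastatic: float = 0.5
    permissive_switch_rate_localized: float = 0.1
    organ_divergence: float = 0.25  # fraction of bins where organs' normals differ
    emt_bin_fraction: float = 0.15
    de_gene_fraction: float = 425 / 1200  # 232 E + 193 M out of 1200 genes
    effect_size_log2: float = 2.0
    dispersion: float = 0.1
    n_genes: int = 1200
    n_localized: int = 2
    n_metastatic: int = 2
    n_secondary_cancers: int = 2
    include_decoy_organ: bool = False
    primary_organ: str = "breast"
    secondary_organ: str = "lung"
    decoy_organ: str = "brain"
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "switch_rate_cancer": self.switch_rate_cancer,
            "permissive_switch_rate_metastatic": self.permissive_switch_rate_metastatic,
            "permissive_switch_rate_localized": self.permissive_switch_rate_localized,
            "organ_divergence": self.organ_divergence,
            "emt_bin_fraction": self.emt_bin_fraction,
            "de_gene_fraction": self.de_gene_fraction,
            "shared_switch_fraction": self.shared_switch_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be positive")
        if not 0.0 < self.checkerboard_strength < 1.0:
            raise ConfigError("checkerboard_strength must lie in (0, 1)")
        if self.n_localized + self.n_metastatic < 2:
            raise ConfigError("need at least 2 primary-organ cancer lines")
        if self.n_bins < 10 or self.bin_size < 1:
            raise ConfigError("n_bins/bin_size too small")
        if self.compartment_block_length < 1:
            raise ConfigError("compartment_block_length must be >= 1 bin")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")


@dataclass
class CellType:
    """One member of the panel with its ground-truth compartment states."""

    name: str
    organ: str
    status: str  # normal | localized | metastatic
    emt_parameter: float
    states: np.ndarray  # +1 (A) / -1 (B) per bin
    planted: np.ndarray | None = None  # per-bin planted class vs own normal


@dataclass
class CellTypePanel:
    """A simulated lineage panel over one bin grid, with planted truth."""

    bins: list[BinIndex]
    cell_types: list[CellType]
    config: SimulationConfig
    divergent_bins: dict[str, np.ndarray] = field(default_factory=dict)
    emt_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    emt_thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        n = len(self.bins)
        for ct in self.cell_types:
            if ct.states.shape != (n,):
                raise ConfigError(f"cell type {ct.name}: states length mismatch")

    def get(self, name: str) -> CellType:
        for ct in self.cell_types:
            if ct.name == name:
                return ct
        raise KeyError(name)

    def normal(self, organ: str) -> CellType:
        for ct in self.cell_types:
            if ct.organ == organ and ct.status == "normal":
                return ct
        raise KeyError(f"no normal cell type for organ {organ!r}")

    def cancers(self, organ: str, status: str | None = None) -> list[CellType]:
        return [
            ct
            for ct in self.cell_types
            if ct.organ == organ
            and ct.status != "normal"
            and (status is None or ct.status == status)
        ]

    def true_state_track(self, name: str) -> StateTrack:
        return StateTrack.from_signs(self.get(name).states, self.bins)

    @property
    def names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]


def _geometric_blocks(n_bins: int, mean_block: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating +1/-1 blocks with geometric lengths (mean ``mean_block``)."""
    states = np.empty(n_bins, dtype=np.int8)
    state = rng.choice([-1, 1])
    i = 0
    p = min(1.0, 1.0 / mean_block)
    while i < n_bins:
        length = rng.geometric(p)
        states[i : i + length] = state
        state = -state
        i += length
    return states


def simulate_panel(
    config: SimulationConfig, chromosome: str = "chr1", ordinal_offset: int = 0
) -> CellTypePanel:
    """Build the cell-type panel's ground-truth compartment state vectors.

    See the module docstring for the planted structure. Per-bin bookkeeping
    is exhaustive: relative to its own organ's normal, every bin of every
    cancer line carries exactly one planted class.
    """
    config.validate()
    cfg = config
    nb = cfg.n_bins
    bins = make_bins(chromosome, nb, cfg.bin_size, ordinal_offset=ordinal_offset)

    normal_primary = _geometric_blocks(
        nb, cfg.compartment_block_length, substream(cfg.seed, chromosome, "blocks")
    )

    # EMT bins: monotone tilt thresholds; direction = flip of the normal state
    rng_emt = substream(cfg.seed, chromosome, "emt-bins")
    n_emt = int(round(cfg.emt_bin_fraction * nb))
    emt_bins = np.sort(rng_emt.choice(nb, size=n_emt, replace=False))
    thresholds = np.full(nb, np.nan)
    thresholds[emt_bins] = rng_emt.uniform(0.05, 0.95, size=n_emt)

    # organ-divergent bins, disjoint from EMT bins (and from each other)
    non_emt = np.setdiff1d(np.arange(nb), emt_bins)
    n_div = int(round(cfg.organ_divergence * nb))
    organs = [cfg.secondary_organ] + ([cfg.decoy_organ] if cfg.include_decoy_organ else [])
    if n_div * len(organs) > non_emt.size:
        raise ConfigError("organ_divergence + emt_bin_fraction leave too few bins")
    divergent: dict[str, np.ndarray] = {}
    pool = non_emt.copy()
    for organ in organs:
        rng_org = substream(cfg.seed, chromosome, "divergence", organ)
        chosen = np.sort(rng_org.choice(pool, size=n_div, replace=False))
        divergent[organ] = chosen
        pool = np.setdiff1d(pool, chosen)

    normals = {cfg.primary_organ: normal_primary}
    for organ in organs:
        vec = normal_primary.copy()
        vec[divergent[organ]] *= -1
        normals[organ] = vec

    # clonal (organ-shared) cancer switches: flipped in every cancer line of
    # the organ, drawn from bins free of other planted structure; private
    # switches make up the rest of switch_rate_cancer
    all_divergent = (
        np.concatenate(list(divergent.values())) if divergent else np.empty(0, int)
    )
    shared_pool = np.setdiff1d(non_emt, all_divergent)
    shared_rate = cfg.switch_rate_cancer * cfg.shared_switch_fraction
    private_rate = cfg.switch_rate_cancer * (1.0 - cfg.shared_switch_fraction)
    shared_flips: dict[str, np.ndarray] = {}
    for organ in normals:
        rng_sh = substream(cfg.seed, chromosome, "shared-switches", organ)
        shared_flips[organ] = shared_pool[rng_sh.random(shared_pool.size) < shared_rate]

    cell_types: list[CellType] = []
    for organ, states in normals.items():
        cell_types.append(CellType(f"{organ}-normal", organ, "normal", 0.0, states))

    def derive_cancer(
        name: str, organ: str, status: str, emt: float, permissive_rate: float | None
    ) -> CellType:
        rng = substream(cfg.seed, chromosome, "cancer", name)
        normal = normals[organ]
        states = normal.copy()
        planted = np.full(nb, PLANT_STABLE, dtype="<U20")
        # EMT tilt: bin flips once the line's EMT parameter crosses its threshold
        flip = np.zeros(nb, dtype=bool)
        flip[emt_bins] = emt >= thresholds[emt_bins]
        planted[emt_bins] = np.where(flip[emt_bins], PLANT_EMT_FLIP, PLANT_EMT_STABLE)
        states[flip] *= -1
        background = np.ones(nb, dtype=bool)
        background[emt_bins] = False
        if organ == cfg.primary_organ:
            # permissive flips toward the secondary organ at its divergent bins
            elig = divergent[cfg.secondary_organ]
            switched = elig[rng.random(elig.size) < (permissive_rate or 0.0)]
            states[switched] = normals[cfg.secondary_organ][switched]
            planted[elig] = PLANT_PERMISSIVE_RETAINED
            planted[switched] = PLANT_PERMISSIVE_FLIP
            background[elig] = False
            if cfg.include_decoy_organ:
                dec = divergent[cfg.decoy_organ]
                planted[dec] = PLANT_DECOY_DIVERGENT
                background[dec] = False
        else:
            # divergent bins are ordinary background for non-primary organs
            pass
        # clonal switches shared by every cancer line of this organ
        shared = shared_flips[organ]
        states[shared] *= -1
        planted[shared] = PLANT_SHARED
        background[shared] = False
        # private, unstructured switches on the remaining background bins
        bg = np.flatnonzero(background)
        flipped = bg[rng.random(bg.size) < private_rate]
        states[flipped] *= -1
        planted[flipped] = PLANT_RANDOM
        return CellType(name, organ, status, emt, states, planted)

    # primary cancer lines span the EMT gradient; metastatic lines sit at the
    # mesenchymal end (matching how lung-metastasis-derived lines behave)
    n_pc = cfg.n_localized + cfg.n_metastatic
    emt_grid = np.linspace(0.0, 1.0, n_pc) if n_pc > 1 else np.array([0.5])
    for i in range(cfg.n_localized):
        cell_types.append(
            derive_cancer(
                f"{cfg.primary_organ}-loc{i + 1}",
                cfg.primary_organ,
                "localized",
                float(emt_grid[i]),
                cfg.permissive_switch_rate_localized,
            )
        )
    for i in range(cfg.n_metastatic):
        cell_types.append(
            derive_cancer(
                f"{cfg.primary_organ}-met{i + 1}",
                cfg.primary_organ,
                "metastatic",
                float(emt_grid[cfg.n_localized + i]),
                cfg.permissive_switch_rate_metastatic,
            )
        )
    for organ in organs:
        for i in range(cfg.n_secondary_cancers):
            cell_types.append(
                derive_cancer(f"{organ}-loc{i + 1}", organ, "localized", 0.5, None)
            )

    return CellTypePanel(bins, cell_types, cfg, divergent, emt_bins, thresholds)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def _as_signs(states) -> np.ndarray:
    if isinstance(states, StateTrack):
        return states.signs()
    return np.asarray(states)


def expected_contact_matrix(states, config: SimulationConfig) -> np.ndarray:
    """Noise-free expected contact map for a +1/-1 state vector.

    E[i,j] = C (|i-j|+1)^-alpha (1+delta) for same-compartment pairs and
    (1-delta) otherwise, with C chosen so the sum over unordered pairs
    (i < j) equals ``config.depth``. The diagonal is zero.
    """
    signs = _as_signs(states)
    n = signs.size
    if n != config.n_bins:
        raise ConfigError(f"states length {n} != n_bins {config.n_bins}")
    delta = config.checkerboard_strength
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    decay = (dist + 1.0) ** (-config.decay_exponent)
    same = np.equal.outer(signs, signs)
    expected = decay * np.where(same, 1.0 + delta, 1.0 - delta)
    np.fill_diagonal(expected, 0.0)
    total = expected[np.triu_indices(n, k=1)].sum()
    return expected * (config.depth / total)


def simulate_contact_matrix(
    states, config: SimulationConfig, rng: np.random.Generator | None = None
) -> ContactMatrix:
    """Draw a Poisson contact matrix around :func:`expected_contact_matrix`."""
    config.validate()
    signs = _as_signs(states)
    if rng is None:
        rng = substream(config.seed, "contacts")
    expected = expected_contact_matrix(signs, config)
    n = signs.size
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    draws = rng.poisson(expected[iu]).astype(float)
    counts[iu] = draws
    counts = counts + counts.T
    if isinstance(states, StateTrack):
        bins = list(states.bins)
    else:
        bins = make_bins("chr1", n, config.bin_size)
    return ContactMatrix(counts, bins)


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

def simulate_genes(
    panel: CellTypePanel, config: SimulationConfig | None = None
) -> tuple[list[GeneAnnotation], GeneSetCollection, pd.DataFrame]:
    """Plant a gene annotation decoupled from compartment switches.

    Differentially expressed genes (the epithelial and mesenchymal signature
    sets) are placed only in bins that are A in every cell type; the
    remaining, expression-flat genes are scattered uniformly, so bins that
    switch compartment carry only flat genes. Returns (annotation, gene
    sets named ``E``/``M``, per-gene truth table).
    """
    cfg = config or panel.config
    rng = substream(cfg.seed, "genes")
    nb = len(panel.bins)
    all_states = np.vstack([ct.states for ct in panel.cell_types])
    constitutive_a = np.flatnonzero((all_states > 0).all(axis=0))
    if constitutive_a.size == 0:
        raise ConfigError("no constitutive-A bins to host differential genes")

    n_de = int(round(cfg.de_gene_fraction * cfg.n_genes))
    n_epi = int(round(n_de * 232 / 425))
    n_mes = n_de - n_epi
    n_flat = cfg.n_genes - n_de
    if n_flat < 0:
        raise ConfigError("de_gene_fraction and n_genes give negative flat genes")

    ever_b = np.flatnonzero((all_states < 0).any(axis=0))

    def place(prefix: str, count: int, host_bins: np.ndarray) -> list[tuple[str, int]]:
        chosen = rng.choice(host_bins, size=count, replace=True)
        return [(f"{prefix}{i + 1:04d}", int(b)) for i, b in enumerate(chosen)]

    placements = (
        [(g, b, "E") for g, b in place("EPI", n_epi, constitutive_a)]
        + [(g, b, "M") for g, b in place("MES", n_mes, constitutive_a)]
        + [(g, b, "none") for g, b in place("GEN", n_flat, np.arange(nb))]
    )

    genes: list[GeneAnnotation] = []
    rows = []
    for gene_id, bin_idx, set_name in placements:
        b = panel.bins[bin_idx]
        width = b.end - b.start
        length = int(rng.integers(max(2, width // 50), max(3, width // 5)))
        start = int(b.start + rng.integers(0, max(1, width - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_id, gene_id, b.chromosome, start, start + length, strand))
        rows.append(
            {
                "gene_id": gene_id,
                "set": set_name,
                "differential": set_name != "none",
                "bin": bin_idx,
                "bin_class": "constitutive_A" if bin_idx in set(constitutive_a) else (
                    "switching" if bin_idx in set(ever_b) else "other"
                ),
            }
        )

    sets = GeneSetCollection()
    sets.add("E", [g for g, _, s in placements if s == "E"])
    sets.add("M", [g for g, _, s in placements if s == "M"])
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genes, sets, truth


def simulate_expression(
    panel: CellTypePanel,
    genes: list[GeneAnnotation],
    gene_sets: GeneSetCollection,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Expression counts (genes x cell types) with a planted EMT axis.

    Per gene g and cell type with EMT parameter e, the mean of log2(count)
    is ``base_g + effect_size_log2 * e`` for mesenchymal-set genes,
    ``base_g - effect_size_log2 * e`` for epithelial-set genes, and
    ``base_g`` otherwise; counts are drawn gamma-Poisson (negative-binomial
    style) with the configured dispersion.
    """
    cfg = config or panel.config
    cfg.validate()
    annotated = {g.gene_id for g in genes}
    e_set, m_set = set(gene_sets["E"]), set(gene_sets["M"])
    for name, members in (("E", e_set), ("M", m_set)):
        missing = members - annotated
        if missing:
            warnings.warn(
                f"{len(missing)} {name}-set genes absent from annotation; skipped"
            )
    gene_ids = [g.gene_id for g in genes]
    if not gene_ids:
        raise ConfigError("no annotated genes to simulate expression for")

    rng_base = substream(cfg.seed, "expression", "baseline")
    base_log2 = rng_base.normal(6.0, 1.5, size=len(gene_ids))
    direction = np.array(
        [1.0 if g in m_set else (-1.0 if g in e_set else 0.0) for g in gene_ids]
    )

    table = {}
    for ct in panel.cell_types:
        rng = substream(cfg.seed, "expression", ct.name)
        mean_log2 = base_log2 + cfg.effect_size_log2 * ct.emt_parameter * direction
        mean = np.power(2.0, mean_log2)
        if cfg.dispersion > 0:
            lam = rng.gamma(1.0 / cfg.dispersion, mean * cfg.dispersion)
        else:
            lam = mean
        table[ct.name] = rng.poisson(lam)
    return pd.DataFrame(table, index=pd.Index(gene_ids, name="gene_id"))


def concat_panels(panels: list[CellTypePanel]) -> CellTypePanel:
    """Concatenate per-chromosome panels into one genome-wide panel.

    Panels must share cell-type composition (names, organs, statuses, EMT
    parameters); bins are re-numbered consecutively.
    """
    if not panels:
        raise ConfigError("no panels to concatenate")
    first = panels[0]
    for p in panels[1:]:
        if p.names != first.names:
            raise ConfigError("panels have different cell-type compositions")
    bins: list[BinIndex] = []
    offset = 0
    offsets = []
    for p in panels:
        offsets.append(offset)
        for b in p.bins:
            bins.append(BinIndex(b.chromosome, b.start, b.end, offset + (b.ordinal - p.bins[0].ordinal)))
        offset += len(p.bins)
    cell_types = []
    for i, ct in enumerate(first.cell_types):
        states = np.concatenate([p.cell_types[i].states for p in panels])
        planted = (
            np.concatenate([p.cell_types[i].planted for p in panels])
            if ct.planted is not None
            else None
        )
        cell_types.append(
            CellType(ct.name, ct.organ, ct.status, ct.emt_parameter, states, planted)
        )
    divergent = {
        organ: np.concatenate(
            [p.divergent_bins[organ] + off for p, off in zip(panels, offsets)]
        )
        for organ in first.divergent_bins
    }
    emt_bins = np.concatenate([p.emt_bins + off for p, off in zip(panels, offsets)])
    thresholds = np.concatenate([p.emt_thresholds for p in panels])
    return CellTypePanel(bins, cell_types, first.config, divergent, emt_bins, thresholds)
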