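"""End-to-end drivers tying the pipeline stages together on synthetic panels.

Each experiment here generates data with :mod:`oto.synthetic`, runs the
relevant analysis stages, and returns both the estimates and the values the
planted truth implies, so callers can measure recovery. The same functions
back the ``analysis/`` scripts, the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .compartments import (
    call_states,
    compartment_eigenvector,
    ice_normalize,
    orient_track,
    scale_chromosome,
    select_compartment_component,
)
from .containers import CompartmentTrack, ContactMatrix, StateTrack
from .emt import nnpca_scores, score_panel
from .organotropism import (
    PermissiveSummary,
    adjusted_permissive,
    compare_target_organs,
    consensus_pair_states,
    cross_states,
    permissive_summary,
    stability_probabilities,
)
from .profiles import (
    ProfileMatrix,
    assemble_profile,
    expression_profile,
    overlap_fraction,
    profile_pca,
    top_loading_bins,
)
from .synthetic import (
    CellTypePanel,
    SimulationConfig,
    concat_panels,
    expected_contact_matrix,
    simulate_contact_matrix,
    simulate_expression,
    simulate_genes,
    simulate_panel,
    substream,
)

__all__ = [
    "call_compartments",
    "simulate_genome",
    "call_panel_compartments",
    "compartment_recovery",
    "organotropism_experiment",
    "cross_organ_experiment",
    "emt_gradient_experiment",
    "overlap_experiment",
]


def call_compartments(
    matrix: ContactMatrix,
    covariate: np.ndarray,
    target_total: float = 1e6,
    pc: str = "pc1",
) -> tuple[CompartmentTrack, StateTrack]:
    """Full per-chromosome chain: ICE -> scale -> O/E eigenvector -> orient -> call.

    ``pc="auto"`` picks among the first three eigenvectors the one best
    correlated with the covariate; the default uses the leading one.
    """
    balanced, _ = ice_normalize(matrix)
    scaled = scale_chromosome(balanced, target_total)
    if pc == "auto":
        track, _ = select_compartment_component(scaled, covariate)
    else:
        track = compartment_eigenvector(scaled)
    oriented = orient_track(track, covariate)
    return oriented, call_states(oriented)


def simulate_genome(
    config: SimulationConfig, n_chromosomes: int = 1
) -> tuple[CellTypePanel, list[CellTypePanel]]:
    """Simulate per-chromosome panels and their genome-wide concatenation."""
    panels = [
        simulate_panel(config, chromosome=f"chr{i + 1}") for i in range(n_chromosomes)
    ]
    return concat_panels(panels) if n_chromosomes > 1 else panels[0], panels


@dataclass
class PanelCalls:
    """Called compartment tracks/states for every panel member, plus truth."""

    panel: CellTypePanel  # genome-wide
    tracks: dict[str, CompartmentTrack]
    states: dict[str, StateTrack]
    accuracy: dict[str, float]  # called-vs-planted sign agreement per cell type

    def truth_states(self, name: str) -> StateTrack:
        return self.panel.true_state_track(name)


def call_panel_compartments(
    config: SimulationConfig, n_chromosomes: int = 1, noiseless: bool = False
) -> PanelCalls:
    """Simulate contact maps for every cell type and call their compartments.

    Orientation uses the planted-truth state vector of each cell type as
    covariate (the synthetic stand-in for gene density). ``noiseless``
    skips Poisson sampling and uses the expected contact map.
    """
    genome, panels = simulate_genome(config, n_chromosomes)
    tracks: dict[str, CompartmentTrack] = {}
    states: dict[str, StateTrack] = {}
    accuracy: dict[str, float] = {}
    for idx, ct in enumerate(genome.cell_types):
        per_chrom_values = []
        for panel in panels:
            member = panel.cell_types[idx]
            if noiseless:
                counts = expected_contact_matrix(member.states, config)
                matrix = ContactMatrix(counts, list(panel.bins))
            else:
                rng = substream(
                    config.seed, panel.bins[0].chromosome, "contacts", member.name
                )
                matrix = simulate_contact_matrix(
                    StateTrack.from_signs(member.states, panel.bins), config, rng
                )
            track, _ = call_compartments(matrix, member.states.astype(float))
            per_chrom_values.append(track.values)
        values = np.concatenate(per_chrom_values)
        track = CompartmentTrack(values, list(genome.bins), oriented=True, orientation_r=1.0)
        called = call_states(track)
        tracks[ct.name] = track
        states[ct.name] = called
        called_mask = called.states != "NA"
        agree = (called.signs() == ct.states) & called_mask
        accuracy[ct.name] = float(agree.sum() / max(1, called_mask.sum()))
    return PanelCalls(genome, tracks, states, accuracy)


def compartment_recovery(config: SimulationConfig, noiseless: bool = False) -> float:
    """Sign agreement between called and planted states for the primary-organ
    normal epithelium on one simulated chromosome."""
    panel = simulate_panel(config)
    normal = panel.normal(config.primary_organ)
    if noiseless:
        matrix = ContactMatrix(expected_contact_matrix(normal.states, config), list(panel.bins))
    else:
        rng = substream(config.seed, "chr1", "contacts", normal.name)
        matrix = simulate_contact_matrix(
            StateTrack.from_signs(normal.states, panel.bins), config, rng
        )
    _, called = call_compartments(matrix, normal.states.astype(float))
    ok = called.states != "NA"
    return float(((called.signs() == normal.states) & ok).sum() / max(1, ok.sum()))


def _group_summary(
    states: dict[str, StateTrack],
    panel: CellTypePanel,
    cancer_names: list[str],
) -> PermissiveSummary:
    cfg = panel.config
    primary_pairs = consensus_pair_states(
        states[f"{cfg.primary_organ}-normal"], [states[n] for n in cancer_names]
    )
    sec_normal = states[f"{cfg.secondary_organ}-normal"]
    sec_cancers = [states[ct.name] for ct in panel.cancers(cfg.secondary_organ)]
    secondary_pairs = consensus_pair_states(sec_normal, sec_cancers)
    cross = cross_states(primary_pairs, secondary_pairs)
    summary = permissive_summary(cross)
    probs = stability_probabilities(sec_normal, sec_cancers)
    return adjusted_permissive(summary, probs)


@dataclass
class OrganotropismResult:
    """Estimated and truth-derived permissive summaries per status group."""

    estimated: dict[str, PermissiveSummary]  # keys: metastatic, localized
    truth: dict[str, PermissiveSummary]
    calls: PanelCalls


def organotropism_experiment(
    config: SimulationConfig, n_chromosomes: int = 1
) -> OrganotropismResult:
    """Permissive fractions of metastatic vs localized groups, estimated from
    called compartments and recomputed on planted truth states."""
    calls = call_panel_compartments(config, n_chromosomes)
    panel = calls.panel
    cfg = panel.config
    truth_states = {ct.name: panel.true_state_track(ct.name) for ct in panel.cell_types}
    groups = {
        "metastatic": [ct.name for ct in panel.cancers(cfg.primary_organ, "metastatic")],
        "localized": [ct.name for ct in panel.cancers(cfg.primary_organ, "localized")],
    }
    estimated = {g: _group_summary(calls.states, panel, names) for g, names in groups.items()}
    truth = {g: _group_summary(truth_states, panel, names) for g, names in groups.items()}
    return OrganotropismResult(estimated, truth, calls)


@dataclass
class CrossOrganResult:
    estimated: dict[str, PermissiveSummary]  # organ -> adjusted summary
    truth: dict[str, PermissiveSummary]
    calls: PanelCalls

    @staticmethod
    def adjusted_total(summary: PermissiveSummary) -> float:
        return summary.adjusted_AB_BB_percent + summary.adjusted_BA_AA_percent


def cross_organ_experiment(
    config: SimulationConfig, n_chromosomes: int = 1
) -> CrossOrganResult:
    """Adjusted permissive percentages of the metastatic group toward the
    true target organ vs a decoy organ with no planted permissive switches."""
    config = replace(config, include_decoy_organ=True)
    calls = call_panel_compartments(config, n_chromosomes)
    panel = calls.panel
    cfg = panel.config

    def run(states: dict[str, StateTrack]) -> dict[str, PermissiveSummary]:
        met = [states[ct.name] for ct in panel.cancers(cfg.primary_organ, "metastatic")]
        organ_panels = {}
        for organ in (cfg.secondary_organ, cfg.decoy_organ):
            normal = states[f"{organ}-normal"]
            cancers = [states[ct.name] for ct in panel.cancers(organ)]
            organ_panels[organ] = (normal, cancers)
        return compare_target_organs(
            states[f"{cfg.primary_organ}-normal"], met, organ_panels
        )

    truth_states = {ct.name: panel.true_state_track(ct.name) for ct in panel.cell_types}
    return CrossOrganResult(run(calls.states), run(truth_states), calls)


@dataclass
class EMTGradientResult:
    spearman_compartment_pc1: float
    spearman_nnpca: float
    spearman_enrichment: float
    spearman_enrichment_vs_nnpca: float
    scores_enrichment: pd.DataFrame
    scores_nnpca: pd.DataFrame
    compartment_profile: ProfileMatrix


def gradient_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for the planted EMT gradient panel: eight
    primary-organ cancer lines spanning [0, 1], no organ divergence."""
    base = dict(
        n_localized=4,
        n_metastatic=4,
        organ_divergence=0.0,
        permissive_switch_rate_metastatic=0.0,
        permissive_switch_rate_localized=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def emt_gradient_experiment(config: SimulationConfig) -> EMTGradientResult:
    """Orderings of the planted EMT gradient recovered by (i) PC1 of the
    called compartment profile, (ii) nnPCA M-E, (iii) enrichment M-E."""
    calls = call_panel_compartments(config)
    panel = calls.panel
    cfg = panel.config
    cancer_names = [ct.name for ct in panel.cancers(cfg.primary_organ)]
    emt = np.array([panel.get(n).emt_parameter for n in cancer_names])

    profile = assemble_profile({n: calls.tracks[n] for n in cancer_names})
    pca = profile_pca(profile, n_components=2)
    pc1 = pca.scores[:, 0]
    rho_pc1 = abs(float(spearmanr(pc1, emt)[0]))

    genes, sets, _ = simulate_genes(panel, cfg)
    expression = simulate_expression(panel, genes, sets, cfg)
    expr_cancers = expression[cancer_names]
    nn = nnpca_scores(expr_cancers, sets)
    enr = score_panel(expr_cancers, sets)
    rho_nn = float(spearmanr(nn.table["combined"].to_numpy(), emt)[0])
    rho_enr = float(spearmanr(enr.table["combined"].to_numpy(), emt)[0])
    rho_cross = float(
        spearmanr(
            enr.table["combined"].to_numpy(), nn.table["combined"].to_numpy()
        )[0]
    )
    return EMTGradientResult(
        rho_pc1, rho_nn, rho_enr, rho_cross, enr.table, nn.table, profile
    )


@dataclass
class OverlapResult:
    positive_overlap: float  # compartment-PC1 positive bins vs expression-gene bins
    negative_overlap: float
    combined_overlap: float
    n_bins: int


def overlap_experiment(
    config: SimulationConfig, n_chromosomes: int = 3, k: int = 100
) -> OverlapResult:
    """Bin-level overlap between the compartment-PC1 top loading bins and
    the bins hosting the expression-PC1 top loading genes.

    The generator decouples the two by design: differential genes live in
    constitutive-A bins while compartment-switching bins carry flat genes,
    so this overlap measures how orthogonal the two signatures are.
    """
    calls = call_panel_compartments(config, n_chromosomes)
    panel = calls.panel
    cfg = panel.config
    names = [ct.name for ct in panel.cell_types]

    comp_profile = assemble_profile({n: calls.tracks[n] for n in names})
    comp_pca = profile_pca(comp_profile, n_components=1)
    comp_sel = top_loading_bins(comp_pca, comp_profile, component=0, k=k)

    genes, sets, truth = simulate_genes(panel, cfg)
    expression = simulate_expression(panel, genes, sets, cfg)
    expr_profile = expression_profile(expression)
    expr_pca = profile_pca(expr_profile, n_components=1)
    expr_sel = top_loading_bins(expr_pca, expr_profile, component=0, k=k)

    gene_bin = truth["bin"].to_dict()
    expr_bins = {
        gene_bin[g] for g in expr_sel.positive_features + expr_sel.negative_features
    }
    pos = overlap_fraction(comp_sel.positive_features, expr_bins)
    neg = overlap_fraction(comp_sel.negative_features, expr_bins)
    both = overlap_fraction(
        set(comp_sel.positive_features) | set(comp_sel.negative_features), expr_bins
    )
    return OverlapResult(pos, neg, both, len(panel.bins))
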