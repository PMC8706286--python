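"""Synthetic voltammogram worlds with a known phylogeny.

The generator encodes the chemotaxonomic premise that drives
fingerprint-based phylogenetics: compound concentrations are heritable,
so chemically (and hence electrochemically) similar species are close on
the tree.  Concretely:

* a rooted ultrametric pure-birth (Yule) tree is simulated for the
  ingroup, another for the outgroup, and the two are joined at a root
  whose child branches are stretched by ``outgroup_branch_scale`` — so
  every outgroup–ingroup path exceeds any within-group path;
* log-concentrations of a panel of electroactive compounds evolve by
  Brownian motion along the branches (geometric Brownian motion of the
  concentrations themselves, which therefore stay positive);
* each tip's concentrations are rendered into DPV traces under the two
  extraction/electrolyte conditions.  A compound contributes a Gaussian
  oxidation peak at a condition-dependent potential, weighted by its
  concentration and its per-condition extraction efficiency.  Replicates
  differ by a lognormal amplitude scale and additive Gaussian noise —
  never by a peak-potential shift, matching how replicate DPV recordings
  actually vary.

All randomness flows from one root seed through named per-stage
substreams, so e.g. per-trace noise does not change when unrelated
stages are re-parameterized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import CANONICAL_GRID, CONDITIONS, PotentialGrid, Voltammogram
from .errors import InvalidArgumentError

# Named substream tags: mixing them into the seed sequence keeps the
# stages' random streams independent and individually reproducible.
_STAGE_TREE = 11
_STAGE_PANEL = 23
_STAGE_TRAITS = 37
_STAGE_TRACE = 53

#: Unscaled stem length below each root child, multiplied by
#: ``outgroup_branch_scale`` (the ingroup crown has unit depth before
#: the final rescaling).
_STEM_BASE = 0.3

#: Depth of the outgroup crown relative to the ingroup crown.  The
#: outgroup is kept internally coherent — it stands for a set of taxa
#: sharing derived non-ingroup chemistry — while its stem places it far
#: from every ingroup lineage.
_OUT_CROWN = 0.2


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(list(keys))


# ---------------------------------------------------------------------------
# Tree simulation


def _yule_subtree(n: int, rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Forward-time pure-birth subtree with ``n`` extant ultrametric tips.

    Returns (root node, depth). For n == 1 the subtree is a single tip of
    depth 0.
    """
    if n == 1:
        return dendropy.Node(), 0.0
    root = dendropy.Node()
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
    birth = {id(c): 0.0 for c in first}
    active = list(first)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = t - birth[id(parent)]
        kids = [dendropy.Node(), dendropy.Node()]
        for k in kids:
            parent.add_child(k)
            birth[id(k)] = t
        active.extend(kids)
    depth = t + rng.exponential(1.0 / n)
    for leaf in active:
        leaf.edge.length = depth - birth[id(leaf)]
    return root, depth


def _scale_edges(node: dendropy.Node, factor: float) -> None:
    for nd in node.preorder_iter():
        if nd.edge.length is not None:
            nd.edge.length *= factor


def simulate_tree(
    n_ingroup: int,
    n_outgroup: int,
    outgroup_branch_scale: float = 5.0,
    seed: int = 0,
) -> dendropy.Tree:
    """Simulate the true phylogeny: Yule ingroup + Yule outgroup.

    Tips are labeled ``IN01..`` and ``OUT01..``; the tree is rooted,
    binary, ultrametric and rescaled to unit depth.  The two root-child
    stems are stretched by ``outgroup_branch_scale`` so the
    outgroup–ingroup divergence dominates all within-group divergences.
    """
    if n_ingroup < 2 or n_outgroup < 1:
        raise InvalidArgumentError("need n_ingroup >= 2 and n_outgroup >= 1")
    if outgroup_branch_scale <= 0:
        raise InvalidArgumentError("outgroup_branch_scale must be positive")
    rng = _rng(seed, _STAGE_TREE)

    in_root, in_depth = _yule_subtree(n_ingroup, rng)
    out_root, out_depth = _yule_subtree(n_outgroup, rng)
    if in_depth > 0:
        _scale_edges(in_root, 1.0 / in_depth)
    if out_depth > 0:
        _scale_edges(out_root, _OUT_CROWN / out_depth)
    in_depth = 1.0
    out_depth = _OUT_CROWN if n_outgroup > 1 else 0.0

    stem = _STEM_BASE * outgroup_branch_scale
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.add_child(in_root)
    tree.seed_node.add_child(out_root)
    in_root.edge.length = stem
    # Pad the outgroup stem so every tip sits at the same total depth.
    out_root.edge.length = stem + (in_depth - out_depth)

    total = in_depth + stem
    _scale_edges(tree.seed_node, 1.0 / total)

    for i, leaf in enumerate(nd for nd in in_root.leaf_iter()):
        leaf.taxon = tns.new_taxon(label=f"IN{i + 1:02d}")
    for i, leaf in enumerate(nd for nd in out_root.leaf_iter()):
        leaf.taxon = tns.new_taxon(label=f"OUT{i + 1:02d}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_outgroup(label: str) -> bool:
    return label.startswith("OUT")


def _node_depths(tree: dendropy.Tree) -> tuple[dict[int, float], float]:
    depth_of: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth_of[id(nd)] = depth_of[id(nd.parent_node)] + (nd.edge.length or 0.0)
    total = max(depth_of[id(leaf)] for leaf in tree.leaf_node_iter())
    return depth_of, total


def true_clades(
    tree: dendropy.Tree, window: tuple[float, float] = (0.05, 0.95)
) -> dict[str, int]:
    """Planted clade labels via the largest diversification gap.

    The tree is cut at a single height: the midpoint of the widest
    interval (within ``window``, expressed as fractions of the crown
    depth, i.e. the depth below the root's children) that contains no
    internal node.  Clades are the lineages crossing that height — the
    groups separated by the longest pause in diversification, the most
    salient clade structure a reader would mark on the dendrogram.
    Labels are 1..k in preorder.
    """
    lo_frac, hi_frac = window
    if not 0.0 <= lo_frac < hi_frac <= 1.0:
        raise InvalidArgumentError("window must satisfy 0 <= lo < hi <= 1")
    depth_of, total = _node_depths(tree)
    crown = total - min(depth_of[id(c)] for c in tree.seed_node.child_nodes())
    heights = sorted(
        total - depth_of[id(nd)]
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    )
    lo, hi = lo_frac * crown, hi_frac * crown
    points = [lo] + [h for h in heights if lo < h < hi] + [hi]
    gaps = [
        (points[i + 1] - points[i], 0.5 * (points[i] + points[i + 1]))
        for i in range(len(points) - 1)
    ]
    _, cut_height = max(gaps)
    cut_depth = total - cut_height

    labels: dict[str, int] = {}
    clade = 0
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        if parent is None:
            continue
        if depth_of[id(nd)] > cut_depth >= depth_of[id(parent)]:
            clade += 1
            for leaf in nd.leaf_iter():
                labels[leaf.taxon.label] = clade
    return labels


# ---------------------------------------------------------------------------
# Trait evolution


def evolve_compounds(
    tree: dendropy.Tree,
    n_compounds: int,
    sigma: float,
    root_values: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Geometric Brownian motion of compound concentrations on the tree.

    Log-concentrations diffuse independently per compound with variance
    ``sigma**2 × branch_length``; tip values are exponentiated, so all
    concentrations are positive.  Returns a taxa × compounds DataFrame.
    """
    if sigma < 0:
        raise InvalidArgumentError("sigma must be non-negative")
    if n_compounds < 1:
        raise InvalidArgumentError("need at least one compound")
    if root_values is None:
        root_values = np.zeros(n_compounds)
    root_values = np.asarray(root_values, dtype=float)
    if root_values.shape != (n_compounds,):
        raise InvalidArgumentError("root_values length must equal n_compounds")
    rng = _rng(seed, _STAGE_TRAITS)
    values: dict[int, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            values[id(nd)] = root_values.copy()
        else:
            bl = nd.edge.length or 0.0
            step = rng.standard_normal(n_compounds) * (sigma * math.sqrt(bl))
            values[id(nd)] = values[id(nd.parent_node)] + step
        if nd.is_leaf():
            rows[nd.taxon.label] = np.exp(values[id(nd)])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = [f"c{j + 1:02d}" for j in range(n_compounds)]
    out.attrs["sigma"] = sigma
    out.attrs["seed"] = seed
    return out


# ---------------------------------------------------------------------------
# Compound panel and trace rendering


@dataclass(frozen=True)
class CompoundSpec:
    """An electroactive compound's per-condition peak parameters.

    ``extraction_efficiency`` folds together how well the solvent extracts
    the compound and how electroactive it is in that electrolyte; an
    efficiency of 0 means the compound is invisible under that condition.
    """

    compound_id: str
    peak_potential: Mapping[str, float]
    peak_width: Mapping[str, float]
    extraction_efficiency: Mapping[str, float]
    root_log_concentration: float = 0.0

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            for m, name in (
                (self.peak_potential, "peak_potential"),
                (self.peak_width, "peak_width"),
                (self.extraction_efficiency, "extraction_efficiency"),
            ):
                if cond not in m:
                    raise InvalidArgumentError(f"{name} missing condition {cond!r}")
            if not 0.0 <= self.peak_potential[cond] <= 1.3:
                raise InvalidArgumentError("peak potential must lie in [0, 1.3] V")
            if self.peak_width[cond] <= 0:
                raise InvalidArgumentError("peak width must be positive")
            if not 0.0 <= self.extraction_efficiency[cond] <= 1.0:
                raise InvalidArgumentError("extraction efficiency must lie in [0, 1]")


def default_compound_panel(
    n_compounds: int = 150,
    condition_shift: float = 0.06,
    seed: int = 0,
) -> list[CompoundSpec]:
    """Draw a fixed compound world.

    Three compounds sit near 0.4 V (the ascorbate/luteolin region of leaf
    extracts); the rest are scattered over 0.55–1.1 V where catechins,
    coumarins and other phenolics oxidize.  Peaks are deliberately narrow
    (sd 4–7 mV) and numerous: each compound must stay spectrally
    resolvable for the trace to retain the chemical rank that makes
    fingerprints phylogenetically informative.  Acetate-buffer (pH 4.5)
    peaks are shifted anodically by ``condition_shift`` relative to
    phosphate buffer (pH 7.0), as expected for proton-coupled oxidations
    at lower pH.  Extraction efficiencies are drawn once per condition
    from Beta(2, 2); root log-concentrations from N(0, 0.25).
    """
    rng = _rng(seed, _STAGE_PANEL)
    n_low = min(3, n_compounds)
    mu = np.concatenate(
        [
            rng.normal(0.40, 0.015, size=n_low),
            rng.uniform(0.55, 1.1, size=n_compounds - n_low),
        ]
    )
    mu = np.clip(mu, 0.05, 1.3 - condition_shift - 0.05)
    width = rng.uniform(0.004, 0.007, size=n_compounds)
    eff = rng.beta(2.0, 2.0, size=(n_compounds, 2))
    root_log = rng.normal(0.0, 0.25, size=n_compounds)
    panel = []
    for j in range(n_compounds):
        panel.append(
            CompoundSpec(
                compound_id=f"c{j + 1:02d}",
                peak_potential={
                    "water_PBS": float(mu[j]),
                    "ethanol_ABS": float(mu[j] + condition_shift),
                },
                peak_width={c: float(width[j]) for c in CONDITIONS},
                extraction_efficiency={
                    "water_PBS": float(eff[j, 0]),
                    "ethanol_ABS": float(eff[j, 1]),
                },
                root_log_concentration=float(root_log[j]),
            )
        )
    return panel


def render_voltammogram(
    concentrations: Sequence[float],
    compounds: Sequence[CompoundSpec],
    condition: str,
    replicate_amplitude_cv: float = 0.0,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    grid: PotentialGrid = CANONICAL_GRID,
    seed: int | Sequence[int] = 0,
) -> np.ndarray:
    """Render one replicate's current trace.

    current(E) = a · Σ_c conc_c · eff_c · N(E; μ_c, w_c) + baseline(E) + ε(E)

    with ``a`` a per-replicate lognormal amplitude factor of coefficient of
    variation ``replicate_amplitude_cv`` (mean 1), the baseline a smooth
    monotone rise reaching ``baseline_amplitude`` at the anodic end of the
    window, and ε iid Gaussian of sd ``noise_sd``.  Peak potentials never
    move between replicates.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(concentrations) != len(compounds):
        raise InvalidArgumentError(
            f"{len(concentrations)} concentrations for {len(compounds)} compounds"
        )
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    if replicate_amplitude_cv < 0 or noise_sd < 0:
        raise InvalidArgumentError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    potentials = grid.potentials
    signal = np.zeros_like(potentials)
    for conc, spec in zip(concentrations, compounds):
        eff = spec.extraction_efficiency[condition]
        if conc == 0.0 or eff == 0.0:
            continue
        mu = spec.peak_potential[condition]
        w = spec.peak_width[condition]
        signal += conc * eff * np.exp(-0.5 * ((potentials - mu) / w) ** 2)
    if replicate_amplitude_cv > 0:
        s = math.sqrt(math.log1p(replicate_amplitude_cv**2))
        amplitude = math.exp(rng.normal(-0.5 * s * s, s))
    else:
        amplitude = 1.0
    frac = (potentials - grid.start) / (grid.stop - grid.start)
    baseline = baseline_amplitude * frac**2
    current = amplitude * signal + baseline
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=potentials.shape)
    return current


# ---------------------------------------------------------------------------
# Whole-world generation


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic fingerprint world.

    Defaults mirror the study design being emulated: 31 ingroup and 5
    outgroup taxa, two conditions, three replicates per condition, DPV
    window 0–1.3 V.
    """

    n_ingroup: int = 31
    n_outgroup: int = 5
    n_replicates: int = 3
    n_compounds: int = 150
    sigma: float = 0.5
    outgroup_branch_scale: float = 5.0
    condition_shift: float = 0.06
    replicate_amplitude_cv: float = 0.08
    noise_sd: float = 0.01
    baseline_amplitude: float = 0.1
    seed: int = 0
    grid: PotentialGrid = field(default_factory=PotentialGrid)

    def __post_init__(self) -> None:
        if self.n_ingroup + self.n_outgroup < 3:
            raise InvalidArgumentError("need at least 3 taxa in total")
        if self.n_replicates < 1 or self.n_compounds < 1:
            raise InvalidArgumentError("counts must be positive")
        for name in ("sigma", "replicate_amplitude_cv", "noise_sd", "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class SyntheticWorld:
    """A generated dataset plus its ground truth."""

    panel: list[Voltammogram]
    tree: dendropy.Tree
    concentrations: pd.DataFrame
    compounds: list[CompoundSpec]
    config: SimulationConfig


def generate_dataset(config: SimulationConfig) -> SyntheticWorld:
    """Simulate tree, traits and all traces for one world.

    Emits ``n_taxa × 2 conditions × n_replicates`` voltammograms.  Each
    trace draws from its own substream keyed by (taxon, condition,
    replicate), so panels are reproducible trace-by-trace.
    """
    tree = simulate_tree(
        config.n_ingroup, config.n_outgroup, config.outgroup_branch_scale, config.seed
    )
    compounds = default_compound_panel(
        config.n_compounds, config.condition_shift, config.seed
    )
    roots = [c.root_log_concentration for c in compounds]
    conc = evolve_compounds(tree, config.n_compounds, config.sigma, roots, config.seed)
    panel: list[Voltammogram] = []
    for ti, label in enumerate(conc.index):
        for ci, cond in enumerate(CONDITIONS):
            for rep in range(1, config.n_replicates + 1):
                current = render_voltammogram(
                    conc.loc[label].to_numpy(),
                    compounds,
                    cond,
                    replicate_amplitude_cv=config.replicate_amplitude_cv,
                    noise_sd=config.noise_sd,
                    baseline_amplitude=config.baseline_amplitude,
                    grid=config.grid,
                    seed=[config.seed, _STAGE_TRACE, ti, ci, rep],
                )
                panel.append(Voltammogram(label, cond, rep, config.grid, current))
    return SyntheticWorld(panel, tree, conc, compounds, config)
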