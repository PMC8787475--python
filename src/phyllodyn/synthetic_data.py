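"""Seeded generators with planted, recoverable effect structure.

Every downstream stage of the package is exercised against data produced
here: clade-structured ultrametric trees, isolate tables whose traits are
drawn from known clade-conditional distributions, community matrices with
planted forest/host/date effects, exact distance-decay and homogenization
slopes, optional phylogenetically clustered assembly, and plate-image series
of colony spots following logistic growth with a smooth background and
neighbour-competition suppression.

Design of the planted spatial/temporal structure
------------------------------------------------
Communities in "abundance" mode are mixtures of three disjoint taxon blocks:
two gradient endmembers u and v and a sample-specific noise block q.  With
mixture weight w_i on u, the Bray-Curtis dissimilarity between the
relative-abundance profiles of two samples is exactly
``phi * |w_i - w_j| + (1 - phi) * BC(q_i, q_j)``, where ``phi`` is the
endmember share.  Setting ``w_i = w0 + (decay_slope / phi) * x_i`` therefore
plants an expected BC-versus-meters slope equal to ``decay_slope`` exactly,
with the q block contributing distance-independent noise; setting the
within-date spread of w to shrink linearly with date plants the
homogenization slope on the mean-BC-versus-days scale.  "Subset" mode instead
draws presence subsets (uniformly for stochastic assembly, or concentrated
around a random focal lineage with inclusion probability decaying
exponentially in patristic distance, for phylogenetically clustered
assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedEffects",
    "simulate_tree",
    "implied_similarity",
    "simulate_isolates",
    "simulate_communities",
    "make_plate_layout",
    "simulate_plate_images",
    "logistic_intensity",
]

_FORESTS = ("MSH", "SBL")
_HOSTS = ("ACSA", "FAGR", "OSVI", "QURU", "ABBA")
_DATES = (170, 200, 230, 290)  # day of year, June through October


@dataclass
class SimConfig:
    """Study-design parameters for the generators.

    Defaults emulate a two-forest survey: 4 plots per forest along a 1.2 km
    transect, 20 trees per forest, 4 sampling dates spanning the growing
    season, and sequencing depth typical of amplicon libraries.
    """

    seed: int = 0
    n_tips: int = 40
    n_clades: int = 4
    n_samples: int | None = None  # derived from trees x dates when None
    n_taxa: int = 90
    forests: tuple[str, ...] = _FORESTS
    plots_per_forest: int = 4
    trees_per_forest: int = 20  # 2 forests x 20 trees x 4 dates ~ the 179-sample survey scale
    hosts: tuple[str, ...] = _HOSTS
    dates: tuple[int, ...] = _DATES
    transect_m: float = 1200.0
    library_size: tuple[float, float] = (5e3, 5e4)  # log-uniform depth range
    richness_range: tuple[int, int] = (10, 25)  # subset-assembly richness
    support_range: tuple[int, int] = (40, 100)
    clade_ps_range: tuple[float, float] = (0.955, 0.975)
    backbone_ps_range: tuple[float, float] = (0.928, 0.950)

    def __post_init__(self):
        for name in ("n_tips", "n_clades", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clades > self.n_tips:
            raise ValueError("n_clades cannot exceed n_tips")


@dataclass
class PlantedEffects:
    """Known effect sizes planted into the synthetic data.

    clade_factor_assoc maps factor -> clade -> {level: probability}; an
    absent factor or clade falls back to uniform level probabilities.
    forest/host/date effects are standard deviations of per-level, per-taxon
    log abundance multipliers (0 = no effect).  decay_slope is the change in
    expected Bray-Curtis per meter; homogenization_slope the change in mean
    within-date Bray-Curtis per day (negative = communities converging).
    clustering_strength is the exponential rate at which a taxon's inclusion
    probability decays with patristic distance from the sample's focal
    lineage (0 = stochastic assembly).
    """

    clade_factor_assoc: dict | None = None
    forest_effect: float = 0.0
    host_effect: float = 0.0
    date_effect: float = 0.0
    decay_slope: float = 0.0
    homogenization_slope: float = 0.0
    bc_intercept: float = 0.09  # within-date spread component of mean BC at the first date
    mixture_fraction: float = 0.3
    assembly: str = "abundance"  # or "subset"
    clustering_strength: float = 0.0
    growth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.clustering_strength < 0:
            raise ValueError("clustering_strength must be >= 0")
        if self.clade_factor_assoc:
            for factor, per_clade in self.clade_factor_assoc.items():
                for clade, probs in per_clade.items():
                    if abs(sum(probs.values()) - 1.0) > 1e-9:
                        raise ValueError(
                            f"probabilities for {factor}|{clade} must sum to 1"
                        )
        if not 0 < self.mixture_fraction <= 1:
            raise ValueError("mixture_fraction must be in (0, 1]")


# --------------------------------------------------------------------------
# trees


class _SimNode:
    __slots__ = ("height", "children", "label")

    def __init__(self, height, children=(), label=None):
        self.height = height
        self.children = list(children)
        self.label = label


def _random_clade(rng, labels, lo):
    """Random binary subtree over ``labels`` with node heights in (lo, 1)."""
    if len(labels) == 1:
        return _SimNode(1.0, label=labels[0])
    h = rng.uniform(lo, lo + 0.95 * (1.0 - lo))
    k = int(rng.integers(1, len(labels)))
    left = _random_clade(rng, labels[:k], h)
    right = _random_clade(rng, labels[k:], h)
    return _SimNode(h, [left, right])


def simulate_tree(config: SimConfig) -> tuple[dendropy.Tree, dict[str, str]]:
    """Generate a clade-structured binary ultrametric tree on the PS scale.

    Tips sit at height 1; within-clade nodes at high similarity (default
    0.955+), between-clade joins deeper (default 0.928-0.950), so within-
    clade pairwise similarity always exceeds between-clade similarity.
    Internal node labels carry synthetic support percentages.

    Returns the tree (node attribute ``ps_height`` set, so it can be sliced
    directly) and the planted tip -> clade assignment.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_tips, config.n_clades
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    tips = [f"iso{i + 1:03d}" for i in range(n)]
    clades: dict[str, str] = {}
    roots = []
    start = 0
    lo_c, hi_c = config.clade_ps_range
    for ci, size in enumerate(sizes):
        clade_tips = tips[start : start + size]
        start += size
        name = f"C{ci + 1}"
        for t in clade_tips:
            clades[t] = name
        crown = rng.uniform(lo_c, hi_c) if size > 1 else 1.0
        if size == 1:
            node = _SimNode(1.0, label=clade_tips[0])
        else:
            h = crown
            kk = int(rng.integers(1, size))
            node = _SimNode(h, [_random_clade(rng, clade_tips[:kk], h),
                                _random_clade(rng, clade_tips[kk:], h)])
        roots.append(node)

    lo_b, hi_b = config.backbone_ps_range
    join_heights = np.sort(rng.uniform(lo_b, hi_b, size=max(0, k - 1)))[::-1]
    for h in join_heights:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        b = roots.pop(j)
        a = roots.pop(i)
        h = min(h, a.height, b.height)
        roots.append(_SimNode(h, [a, b]))
    root = roots[0]

    # convert to dendropy, attaching ps heights, supports, edge lengths
    tree = dendropy.Tree()
    tns = tree.taxon_namespace

    def build(sim_node, d_node):
        d_node.ps_height = sim_node.height
        if not sim_node.children:
            d_node.taxon = tns.new_taxon(label=sim_node.label)
            return
        d_node.label = str(int(rng.integers(config.support_range[0], config.support_range[1] + 1)))
        for child in sim_node.children:
            c = d_node.new_child()
            build(child, c)
            c.edge.length = c.ps_height - d_node.ps_height

    build(root, tree.seed_node)
    tree.seed_node.label = None
    tree.is_rooted = True
    return tree, clades


def implied_similarity(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise similarity implied by a PS-scaled ultrametric tree.

    PS(i, j) = height of the MRCA = 1 - patristic distance / 2.
    """
    from .ecophylo import cophenetic_distances

    d = cophenetic_distances(tree)
    return 1.0 - d / 2.0


# --------------------------------------------------------------------------
# isolates


def _draw_level(rng, levels, probs=None):
    if probs is None:
        return levels[int(rng.integers(len(levels)))]
    p = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
    p = p / p.sum()
    return levels[int(rng.choice(len(levels), p=p))]


def simulate_isolates(
    tree: dendropy.Tree,
    clades: dict[str, str],
    effects: PlantedEffects,
    config: SimConfig,
) -> pd.DataFrame:
    """One isolate per tip, with traits drawn from planted clade conditionals.

    Columns: isolate, C (clade), F (forest), H (host species), D (day of
    year), T_I (isolation temperature, 20 or 30), tree (host tree ID).
    """
    rng = np.random.default_rng(config.seed + 1)
    assoc = effects.clade_factor_assoc or {}
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in clades]
    if missing:
        raise ValueError(f"tips without clade assignment: {missing}")
    for factor, per_clade in assoc.items():
        absent = sorted(set(clades.values()) - set(per_clade))
        if absent:
            raise ValueError(f"clades missing from {factor} association table: {absent}")

    t_levels = (20, 30)
    rows = []
    for tip in tips:
        clade = clades[tip]
        forest = _draw_level(rng, list(config.forests), assoc.get("F", {}).get(clade))
        rows.append(
            {
                "isolate": tip,
                "C": clade,
                "F": forest,
                "H": _draw_level(rng, list(config.hosts)),
                "D": _draw_level(rng, list(config.dates)),
                "T_I": _draw_level(rng, list(t_levels), assoc.get("T_I", {}).get(clade)),
                "tree": f"{forest}-t{int(rng.integers(config.trees_per_forest)) + 1:02d}",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# communities


def _sample_design(config: SimConfig, rng) -> pd.DataFrame:
    """Sample metadata: trees at plot positions along a transect, per date."""
    rows = []
    plot_x = np.linspace(0, config.transect_m, config.plots_per_forest)
    for forest in config.forests:
        # round-robin allocation: plots hold equal tree counts by design,
        # as in a plot-based survey
        tree_plot = np.arange(config.trees_per_forest) % config.plots_per_forest
        tree_x = plot_x[tree_plot] + rng.uniform(-40, 40, size=config.trees_per_forest)
        tree_x = np.clip(tree_x, 0, config.transect_m)
        tree_host = rng.choice(config.hosts, size=config.trees_per_forest)
        for ti in range(config.trees_per_forest):
            for d in config.dates:
                rows.append(
                    {
                        "sample": f"{forest}-t{ti + 1:02d}-d{d}",
                        "F": forest,
                        "P": f"{forest}-p{tree_plot[ti] + 1}",
                        "H": tree_host[ti],
                        "D": d,
                        "x": tree_x[ti],
                        "y": 0.0,
                        "tree": f"{forest}-t{ti + 1:02d}",
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample")
    if config.n_samples is not None:
        if config.n_samples > len(meta):
            raise ValueError(
                f"n_samples={config.n_samples} exceeds the design capacity {len(meta)}"
            )
        keep = rng.choice(len(meta), size=config.n_samples, replace=False)
        meta = meta.iloc[np.sort(keep)]
    return meta


def _factor_multipliers(rng, meta, column, sd, n_taxa):
    levels = meta[column].unique()
    mult = {lv: np.exp(rng.normal(0.0, sd, size=n_taxa)) for lv in levels}
    return np.stack([mult[lv] for lv in meta[column]])


def simulate_communities(
    effects: PlantedEffects,
    config: SimConfig,
    tree: dendropy.Tree | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Community count matrix plus sample metadata with planted structure.

    Returns ``(counts, meta)``: a samples x taxa integer count table and the
    per-sample factor/coordinate table.  See the module docstring for how
    each planted effect maps onto the data.  In "subset" assembly mode the
    taxa are the tree's tips when a tree is supplied (required when
    ``clustering_strength > 0``).
    """
    rng = np.random.default_rng(config.seed + 2)
    meta = _sample_design(config, rng)
    n = len(meta)
    depth = np.exp(
        rng.uniform(np.log(config.library_size[0]), np.log(config.library_size[1]), size=n)
    ).astype(int)

    if effects.assembly == "subset":
        if effects.clustering_strength > 0 and tree is None:
            raise ValueError("clustered assembly requires a tree")
        if tree is not None:
            from .ecophylo import cophenetic_distances

            dist = cophenetic_distances(tree)
            taxa = list(dist.index)
            dm = dist.to_numpy()
        else:
            taxa = [f"tx{i + 1:04d}" for i in range(config.n_taxa)]
            dm = None
        npool = len(taxa)
        kmin, kmax = config.richness_range
        kmax = min(kmax, npool - 1)
        counts = np.zeros((n, npool), dtype=int)
        for s in range(n):
            k = int(rng.integers(kmin, kmax + 1))
            if effects.clustering_strength > 0:
                focal = int(rng.integers(npool))
                w = np.exp(-effects.clustering_strength * dm[focal])
                p = w / w.sum()
                chosen = rng.choice(npool, size=k, replace=False, p=p)
            else:
                chosen = rng.choice(npool, size=k, replace=False)
            probs = rng.dirichlet(np.ones(k))
            counts[s, chosen] = rng.multinomial(depth[s], probs)
        return pd.DataFrame(counts, index=meta.index, columns=taxa), meta

    if effects.assembly != "abundance":
        raise ValueError(f"unknown assembly mode {effects.assembly!r}")

    n_taxa = config.n_taxa
    phi = effects.mixture_fraction
    base = rng.lognormal(0.0, 1.2, size=n_taxa)

    slopes_on = effects.decay_slope != 0 or effects.homogenization_slope != 0
    if slopes_on:
        # single-taxon endmembers keep the per-taxon gradient signal well
        # above counting noise, so the planted slope survives finite
        # sequencing depth with negligible attenuation
        u = np.zeros(n_taxa)
        v = np.zeros(n_taxa)
        u[0] = 1.0
        v[1] = 1.0
        q_block = np.arange(2, n_taxa)

        x = meta["x"].to_numpy()
        d = meta["D"].to_numpy(dtype=float)
        d0 = float(min(config.dates))
        if effects.homogenization_slope != 0:
            # within-date mixture-weight spread: eta ~ U(-a, a) gives
            # E|eta_i - eta_j| = 2a/3, so mean within-date BC changes by
            # exactly homogenization_slope per day (plus the constant
            # q-block baseline)
            spread_bc = effects.bc_intercept + effects.homogenization_slope * (d - d0)
            if (spread_bc < 0).any():
                raise ValueError("homogenization slope drives the spread component below 0")
            a = 1.5 * spread_bc / phi
            if (a > 0.5).any():
                raise ValueError(
                    "within-date spread exceeds the admissible weight range; "
                    "reduce bc_intercept or mixture_fraction demands"
                )
            w = 0.5 + rng.uniform(-1, 1, size=n) * a
        else:
            w = 0.1 + (effects.decay_slope / phi) * x
            if (w < 0).any() or (w > 1).any():
                raise ValueError("decay slope drives mixture weights outside [0, 1]")
        q = np.zeros((n, n_taxa))
        for s in range(n):
            q[s, q_block] = rng.dirichlet(np.full(len(q_block), 0.5))
        probs = phi * (w[:, None] * u + (1 - w[:, None]) * v) + (1 - phi) * q
    else:
        mean = np.tile(base, (n, 1))
        for column, sd in (("F", effects.forest_effect), ("H", effects.host_effect),
                           ("D", effects.date_effect)):
            if sd > 0:
                mean = mean * _factor_multipliers(rng, meta, column, sd, n_taxa)
        probs = mean / mean.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(depth[s], probs[s]) for s in range(n)])
    taxa = [f"tx{i + 1:04d}" for i in range(n_taxa)]
    return pd.DataFrame(counts, index=meta.index, columns=taxa), meta


# --------------------------------------------------------------------------
# plate images


def logistic_intensity(t, Y, k, t_mid):
    """Colony spot intensity under logistic growth."""
    return Y / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t_mid)))


def make_plate_layout(
    n_isolates: int | None = None,
    treatments: tuple[str, ...] = ("P20M20", "P20M30", "P30M20", "P30M30"),
    n_replicates: int = 5,
    grid: tuple[int, int] = (6, 6),
    cell_px: int = 56,
    radius_px: int = 16,
    seed: int = 0,
    isolate_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Randomly spot isolate x treatment replicates onto 6x6-grid plates.

    Isolates are named ``i001..`` unless explicit ``isolate_ids`` are given
    (e.g. tip labels from a simulated tree).  Returns one row per grid
    position across as many plates as needed, with pixel center coordinates;
    unoccupied positions have a null isolate.
    """
    if cell_px < 2 * radius_px:
        raise ValueError("spot spacing below twice the radius: spots would overlap")
    if isolate_ids is None:
        if n_isolates is None:
            raise ValueError("give n_isolates or isolate_ids")
        isolate_ids = [f"i{i + 1:03d}" for i in range(n_isolates)]
    rng = np.random.default_rng(seed)
    wells = [
        f"{iso}|{tr}|{r + 1}"
        for iso in isolate_ids
        for tr in treatments
        for r in range(n_replicates)
    ]
    rng.shuffle(wells)
    per_plate = grid[0] * grid[1]
    n_plates = int(np.ceil(len(wells) / per_plate))
    rows = []
    w = iter(wells)
    for plate in range(n_plates):
        for r in range(grid[0]):
            for c in range(grid[1]):
                try:
                    iso, tr, rep = next(w).split("|")
                    occupied = True
                except StopIteration:
                    iso, tr, rep, occupied = "", "", "0", False
                rows.append(
                    {
                        "plate": f"plate{plate + 1:02d}",
                        "row": r,
                        "col": c,
                        "cx": c * cell_px + cell_px // 2,
                        "cy": r * cell_px + cell_px // 2,
                        "radius": radius_px,
                        "isolate": iso,
                        "treatment": tr,
                        "replicate": int(rep),
                        "occupied": occupied,
                    }
                )
    layout = pd.DataFrame(rows)
    layout.index = [
        f"{p}:{r}:{c}" for p, r, c in zip(layout["plate"], layout["row"], layout["col"])
    ]
    layout.index.name = "spot"
    layout.attrs["grid"] = grid
    layout.attrs["cell_px"] = cell_px
    return layout


def _competition_fixed_point(i_true, coords, c, n_iter=100):
    """Observed intensities under mutual suppression, by fixed-point iteration.

    Solves I_obs = I_true / (1 + c * N) with load N_i = sum_j I_obs_j / d_ij
    over occupied spots j != i (grid-cell distance units).
    """
    if c == 0 or len(i_true) < 2:
        return i_true.copy()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    np.fill_diagonal(w, 0.0)
    i_obs = i_true.copy()
    for _ in range(n_iter):
        load = w @ i_obs
        i_obs = i_true / (1.0 + c * load)
    return i_obs


def simulate_plate_images(
    effects: PlantedEffects,
    layout: pd.DataFrame,
    times: tuple[float, ...] = (7.0, 13.0, 24.0),
    image_px: tuple[int, int] | None = None,
    seed: int = 0,
    params: pd.DataFrame | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Render grayscale plate photos of growing colony spots.

    Each occupied spot's total intensity follows a logistic curve; spots on
    the same plate suppress each other multiplicatively through the
    neighbourhood-load model (coefficient ``effects.growth['competition']``);
    a low-order 2-D polynomial background (amplitude
    ``effects.growth['background']``) and additive Gaussian pixel noise
    (``effects.growth['noise']``, as a fraction of the peak per-pixel spot
    signal) are added.

    Returns ``(images, truth)`` where ``images`` maps (plate, time) to a
    float array and ``truth`` holds per-spot ground-truth Y, k, t_mid, r and
    the pre-/post-competition total intensities at each time.

    Per-isolate-x-treatment growth parameters are shared by replicates; pass
    ``params`` (indexed by "isolate|treatment", columns Y, k, t_mid) to
    control them, e.g. to plant clade effects.
    """
    rng = np.random.default_rng(seed)
    g = effects.growth
    comp = float(g.get("competition", 0.0))
    bg_amp = float(g.get("background", 0.0))
    noise = float(g.get("noise", 0.0))
    cell = layout.attrs.get("cell_px", 56)
    grid = layout.attrs.get("grid", (6, 6))
    if image_px is None:
        image_px = (grid[0] * cell, grid[1] * cell)

    occ = layout[layout["occupied"]]
    keys = sorted(set(occ["isolate"] + "|" + occ["treatment"]))
    if params is None:
        # k and t_mid are drawn jointly with k * t_mid >= 5.5, so the curve's
        # value at inoculation, Y / (1 + exp(k * t_mid)), stays below ~0.4%
        # of the yield: the inoculum is invisible on the plate photos.  The
        # k ceiling keeps the exponential phase inside the day-7-to-13 photo
        # window; faster curves saturate before the second photo and their
        # shape is unidentifiable from this sampling design
        k = rng.uniform(g.get("k_min", 0.45), g.get("k_max", 0.7), len(keys))
        tm_lo = np.maximum(g.get("t_mid_min", 6.0), 5.5 / k)
        tm_hi = g.get("t_mid_max", 13.0)
        params = pd.DataFrame(
            {
                "Y": np.exp(rng.uniform(np.log(g.get("Y_min", 3.0)), np.log(g.get("Y_max", 15.0)),
                                        len(keys))),
                "k": k,
                "t_mid": rng.uniform(tm_lo, np.maximum(tm_hi, tm_lo + 0.1)),
            },
            index=keys,
        )
    truth = occ.copy()
    kk = truth["isolate"] + "|" + truth["treatment"]
    for col in ("Y", "k", "t_mid"):
        truth[col] = params[col].reindex(kk).to_numpy()
    truth["r"] = 1.0 / (truth["t_mid"] + np.log(19.0) / truth["k"])

    area = None
    images: dict = {}
    peak_px = 0.0
    for plate, sub in truth.groupby("plate"):
        coords = sub[["row", "col"]].to_numpy(dtype=float)
        for t in times:
            i_true = logistic_intensity(t, sub["Y"].to_numpy(), sub["k"].to_numpy(),
                                        sub["t_mid"].to_numpy())
            i_obs = _competition_fixed_point(i_true, coords, comp)
            truth.loc[sub.index, f"I_true_t{t:g}"] = i_true
            truth.loc[sub.index, f"I_obs_t{t:g}"] = i_obs

    yy, xx = np.mgrid[0 : image_px[0], 0 : image_px[1]]
    for plate in layout["plate"].unique():
        psub = truth[truth["plate"] == plate]
        # one random smooth background per plate, fixed across times
        cx = xx / image_px[1] - 0.5
        cy = yy / image_px[0] - 0.5
        coef = rng.uniform(-1, 1, size=6)
        bg = coef[0] + coef[1] * cx + coef[2] * cy + coef[3] * cx * cy + coef[4] * cx**2 + coef[5] * cy**2
        bg = bg_amp * (bg - bg.min()) / max(np.ptp(bg), 1e-12) if bg_amp > 0 else np.zeros_like(bg)
        for t in times:
            img = bg.copy()
            for _, spot in psub.iterrows():
                disc = (xx - spot["cx"]) ** 2 + (yy - spot["cy"]) ** 2 <= spot["radius"] ** 2
                area = disc.sum()
                px_val = spot[f"I_obs_t{t:g}"] / area
                img[disc] += px_val
                peak_px = max(peak_px, px_val)
            images[(plate, float(t))] = img

    if noise > 0:
        sigma = noise * peak_px
        for key in images:
            images[key] = images[key] + rng.normal(0.0, sigma, size=images[key].shape)
    return images, truth


def write_plate_images(images: dict, outdir) -> dict:
    """Write plate frames as 16-bit PNGs (one file per plate and time).

    Intensities are scaled by a single shared factor so the brightest pixel
    maps to the top of the 16-bit range; the factor is returned (and stored
    in ``scale.json``) so :func:`read_plate_images` can invert it.
    """
    import imageio.v3 as iio
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak = max(float(img.max()) for img in images.values()) or 1.0
    scale = 65535.0 / peak
    written = {}
    for (plate, t), img in sorted(images.items()):
        path = outdir / f"{plate}_t{t:g}.png"
        data = np.clip(img * scale, 0, 65535).astype(np.uint16)
        iio.imwrite(path, data)
        written[(plate, float(t))] = path
    (outdir / "scale.json").write_text(json.dumps({"scale": scale}))
    return written


def read_plate_images(indir) -> dict:
    """Read a directory written by :func:`write_plate_images` back to floats."""
    import imageio.v3 as iio
    import json
    import re
    from pathlib import Path

    indir = Path(indir)
    scale = json.loads((indir / "scale.json").read_text())["scale"]
    images = {}
    for path in sorted(indir.glob("*.png")):
        m = re.match(r"(.+)_t([0-9.]+)$", path.stem)
        if not m:
            continue
        images[(m.group(1), float(m.group(2)))] = iio.imread(path).astype(float) / scale
    return images
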