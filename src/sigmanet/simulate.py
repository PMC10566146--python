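"""Continuous-space, individual-based forward simulator.

Generates training and validation data with a known dispersal parameter.  The
model is the standard spatial benchmark: hermaphroditic diploids on a square
habitat, non-overlapping generations, with mother-offspring dispersal, mate
choice and local competition all acting at a single interaction scale
``sigma_f``.  The effective dispersal rate — the RMS single-axis displacement
from a child to a randomly chosen parent — is ``sigma_f * sqrt(3/2)``, since
the father contributes the mating displacement on top of offspring dispersal.

Genealogy is recorded into tskit tables during the forward pass (each gamete
is a recombinant of its parent's two haplotypes).  After the forward phase the
tree sequence is simplified to the final generation, the remaining uncoalesced
roots are closed with a coalescent (recapitation), and neutral infinite-sites
mutations are overlaid at a rate auto-tuned to reach a requested SNP count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import tskit
from scipy.spatial import cKDTree

from .exceptions import (
    ExtinctionError,
    InsufficientIndividualsError,
    InsufficientSNPsError,
    InvalidParameterError,
)
from .io import GenotypeMatrix, LocationsTable, write_store

logger = logging.getLogger(__name__)

#: ratio of effective dispersal to the interaction scale: dispersal and mating
#: kernels both have per-axis variance sigma_f^2, and a random parent is the
#: mother or the father with equal probability, giving variance 3/2 sigma_f^2.
EFFECTIVE_SIGMA_FACTOR = math.sqrt(1.5)

#: the competition window extends this many sigma_f from the focal individual
KERNEL_TRUNCATION = 3.0

#: the Gaussian mating kernel is truncated at this many sigma_f.  At 4 sigma
#: the realized mating variance is within 0.1% of sigma_f^2 (keeping the
#: effective-sigma calibration exact), and the wider support keeps the mating
#: graph connected at lower densities than a 3 sigma cutoff would.
MATING_TRUNCATION = 4.0


def draw_sigma_f(low: float, high: float, rng_seed: int) -> float:
    """Draw the interaction scale uniformly from [low, high]."""
    if not 0 <= low < high:
        raise InvalidParameterError(f"need 0 <= low < high, got [{low}, {high}]")
    rng = np.random.default_rng(rng_seed)
    return float(rng.uniform(low, high))


def effective_sigma(sigma_f: float) -> float:
    """Effective dispersal rate sigma = sigma_f * sqrt(3/2)."""
    if sigma_f < 0:
        raise InvalidParameterError(f"sigma_f must be >= 0, got {sigma_f}")
    return sigma_f * EFFECTIVE_SIGMA_FACTOR


@dataclass
class SimParams:
    """Parameters of one forward simulation.

    The benchmark preset is a 50 x 50 habitat at carrying capacity 5 per
    square map unit with a 1e8 bp genome at recombination rate 1e-8; the
    ``desk()`` preset shrinks the habitat for laptop-scale runs.
    """

    sigma_f: float
    habitat_width: float = 50.0
    carrying_capacity: float = 5.0
    genome_length: float = 1e8
    recomb_rate: float = 1e-8
    mutation_rate: float | None = None  # None: auto-tuned to reach min_snps
    min_snps: int = 1000
    n_generations: int | None = None  # None: ceil(10 W / sigma_f), bounded below
    max_generations: int = 200
    #: cap on the population-scaled recombination rate (4 N r L) used while
    #: closing founder lineages with a coalescent.  The recent history that
    #: carries the spatial signal is recorded exactly during the forward
    #: pass; the deep phase mainly sets baseline diversity, so its
    #: genome-wide recombination can be thinned at large map lengths where
    #: the exact coalescent-with-recombination becomes the dominant cost.
    recap_rho_cap: float = 1000.0
    fecundity: float = 2.0  # mean offspring per mother at zero local crowding
    edge: str = "redraw"  # or "reflect"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_f < 0:
            raise InvalidParameterError("sigma_f must be >= 0")
        if self.habitat_width <= 0 or self.carrying_capacity <= 0:
            raise InvalidParameterError("habitat_width and carrying_capacity must be > 0")
        if self.genome_length < 1:
            raise InvalidParameterError("genome_length must be >= 1")
        if self.recomb_rate < 0 or (self.mutation_rate is not None and self.mutation_rate < 0):
            raise InvalidParameterError("rates must be >= 0")
        if self.edge not in ("redraw", "reflect"):
            raise InvalidParameterError(f"edge must be 'redraw' or 'reflect', got {self.edge!r}")

    @property
    def generations(self) -> int:
        """Burn-in length actually used."""
        if self.n_generations is not None:
            return int(self.n_generations)
        if self.sigma_f == 0:
            return min(30, self.max_generations)
        want = math.ceil(10.0 * self.habitat_width / self.sigma_f)
        return int(min(self.max_generations, max(30, want)))

    @classmethod
    def benchmark(cls, sigma_f: float, **kw) -> "SimParams":
        """Full benchmark scale: 50 x 50 habitat, K = 5."""
        return cls(sigma_f=sigma_f, habitat_width=50.0, carrying_capacity=5.0, **kw)

    @classmethod
    def desk(cls, sigma_f: float, **kw) -> "SimParams":
        """Reduced scale for CPU runs: 10 x 10 habitat, K = 5 (census ~500)."""
        kw.setdefault("habitat_width", 10.0)
        kw.setdefault("carrying_capacity", 5.0)
        return cls(sigma_f=sigma_f, **kw)

    @classmethod
    def desk_training(cls, sigma_f: float = 1.0, **kw) -> "SimParams":
        """Reduced-scale conditions for network training benchmarks.

        A 16 x 16 habitat at density 3.5 (census ~900) with a 10-Morgan
        genome.  Density is kept as low as demographic stability allows:
        identifiability of sigma requires Wright's neighbourhood size
        4 pi D sigma^2 to stay well below the census across the whole
        sigma_f ~ U(0.2, 3) range (at higher density the upper half of the
        range is effectively panmictic at this habitat size), while the
        mating graph at sigma_f = 0.2 must stay above the percolation
        threshold, which rules out densities much below 3.5.  The long
        genome decorrelates the recent genealogies of the SNPs, sharpening
        the isolation-by-distance signal per SNP.
        """
        kw.setdefault("habitat_width", 16.0)
        kw.setdefault("carrying_capacity", 3.5)
        kw.setdefault("genome_length", 1e9)
        kw.setdefault("max_generations", 250)
        return cls(sigma_f=sigma_f, **kw)


@dataclass
class SimOutput:
    """One simulated dataset (possibly the full census, possibly a sample)."""

    genotypes: GenotypeMatrix
    locations: LocationsTable
    sigma_true: float
    sigma_f: float
    params: SimParams
    mutation_rate_used: float = float("nan")
    census: int = 0
    #: (n_births, 4) array of mother_x, mother_y, dx, dy for every recorded
    #: birth; the dispersal-kernel diagnostic. Dropped on subsetting.
    births: np.ndarray | None = None


def _overlay_mutations(ts: tskit.TreeSequence, params: SimParams, seed: int):
    """Overlay neutral mutations; auto-tune the rate when not fixed.

    Expected mutation count is rate x total branch area, so the auto-tuned
    rate targets 1.3 x min_snps biallelic sites and doubles on shortfall.
    """
    if params.mutation_rate is not None:
        mts = msprime.sim_mutations(ts, rate=params.mutation_rate, random_seed=seed)
        return mts, params.mutation_rate
    area = ts.segregating_sites(mode="branch", span_normalise=False)
    if area <= 0:
        raise InsufficientSNPsError("tree sequence has zero branch length")
    rate = 1.3 * max(params.min_snps, 1) / area
    for attempt in range(6):
        mts = msprime.sim_mutations(ts, rate=rate, random_seed=seed + attempt)
        n_biallelic = sum(1 for s in mts.sites() if len({m.derived_state for m in s.mutations}) == 1)
        if n_biallelic >= params.min_snps:
            return mts, rate
        rate *= 2.0
    raise InsufficientSNPsError(
        f"could not reach {params.min_snps} SNPs (last rate {rate:.3g})"
    )


def _record_gametes(parent_node0, child_nodes, L, recomb_rate, rng, edge_buf):
    """Record recombinant gametes as edges parent-haplotype -> child node.

    ``parent_node0`` holds the first haplotype node of each gamete's parent
    (the second is ``+1``).  Crossover counts are Poisson(rate * L) with
    uniform breakpoints; segments alternate between the parent's two
    haplotypes starting from a random one.  Fully vectorized: one
    (left, right, parent, child) array is appended per call.
    """
    n_gam = len(child_nodes)
    k = rng.poisson(recomb_rate * L, size=n_gam)
    start = rng.integers(2, size=n_gam)
    total_breaks = int(k.sum())
    if total_breaks == 0:
        edge_buf.append(np.column_stack([
            np.zeros(n_gam), np.full(n_gam, float(L)),
            (parent_node0 + start).astype(float), child_nodes.astype(float),
        ]))
        return
    gid = np.repeat(np.arange(n_gam), k)
    b = rng.uniform(0, L, size=total_breaks)
    order = np.lexsort((b, gid))
    b = b[order]

    nseg = k + 1
    total_seg = int(nseg.sum())
    seg_start = np.cumsum(nseg) - nseg
    seg_idx = np.arange(total_seg) - np.repeat(seg_start, nseg)
    lefts = np.zeros(total_seg)
    rights = np.full(total_seg, float(L))
    # breakpoint j of gamete g closes segment j and opens segment j+1
    br_start = np.cumsum(k) - k
    br_seg = np.repeat(seg_start, k) + (np.arange(total_breaks) - np.repeat(br_start, k))
    rights[br_seg] = b
    lefts[br_seg + 1] = b
    parents = (np.repeat(parent_node0, nseg)
               + (np.repeat(start, nseg) + seg_idx) % 2)
    childs = np.repeat(child_nodes, nseg)
    keep = rights > lefts  # coincident breakpoints yield empty segments
    edge_buf.append(np.column_stack([
        lefts[keep], rights[keep], parents[keep].astype(float),
        childs[keep].astype(float),
    ]))


def _segment_argmax(keys: np.ndarray, groups: np.ndarray, n_groups: int):
    """First index attaining the per-group maximum key (scatter-max).

    Returns (group ids with at least one member, argmax indices)."""
    gmax = np.full(n_groups, -np.inf)
    np.maximum.at(gmax, groups, keys)
    winner = keys >= gmax[groups]
    w_idx = np.nonzero(winner)[0]
    # exact key ties within a group are measure-zero with Gumbel noise, but
    # resolve deterministically to the first winner anyway
    w_groups = groups[w_idx]
    first = np.unique(w_groups, return_index=True)
    return first[0], w_idx[first[1]]


def _disperse(mx, my, sigma, width, edge, rng):
    """Offspring coordinates around mothers at (mx, my), kept in-habitat."""
    n = len(mx)
    if sigma == 0:
        return mx.copy(), my.copy()
    x = mx + rng.normal(0, sigma, size=n)
    y = my + rng.normal(0, sigma, size=n)
    if edge == "reflect":
        # fold back across the boundary (adequate for sigma << width)
        for _ in range(4):
            x = np.abs(x)
            x = width - np.abs(width - x)
            y = np.abs(y)
            y = width - np.abs(width - y)
    else:
        bad = (x < 0) | (x > width) | (y < 0) | (y > width)
        tries = 0
        while bad.any():
            nb = int(bad.sum())
            x[bad] = mx[bad] + rng.normal(0, sigma, size=nb)
            y[bad] = my[bad] + rng.normal(0, sigma, size=nb)
            bad = (x < 0) | (x > width) | (y < 0) | (y > width)
            tries += 1
            if tries > 100:  # pathological sigma >> width: clamp the stragglers
                x = np.clip(x, 0, width)
                y = np.clip(y, 0, width)
                break
    return x, y


def run_simulation(params: SimParams) -> SimOutput:
    """Run the forward simulation and return the full final-generation census.

    Each generation: every individual (as mother) produces a Poisson number of
    offspring with mean damped by local crowding (Gaussian-kernel density at
    scale sigma_f, Beverton-Holt form, equilibrium at the carrying capacity);
    each offspring's father is drawn among neighbours within 3 sigma_f with
    Gaussian weight; the offspring disperses from the mother by a per-axis
    Gaussian of scale sigma_f (redrawn, or reflected, at habitat edges).
    """
    rng = np.random.default_rng(params.seed)
    W = params.habitat_width
    K = params.carrying_capacity
    sig = params.sigma_f
    T = params.generations
    lam0 = params.fecundity

    n0 = max(2, int(round(K * W * W)))
    px = rng.uniform(0, W, size=n0)
    py = rng.uniform(0, W, size=n0)

    # node bookkeeping: individual i of the current generation owns haplotype
    # nodes (node_of[i], node_of[i]+1)
    node_times: list[float] = [float(T)] * (2 * n0)
    node_of = np.arange(n0) * 2
    edge_buf: list[np.ndarray] = []  # (left, right, parent, child) blocks
    births: list[np.ndarray] = []

    radius = KERNEL_TRUNCATION * sig
    mate_radius = MATING_TRUNCATION * sig
    for gen in range(1, T + 1):
        n_cur = len(node_of)
        pos = np.column_stack([px, py])
        tree = cKDTree(pos)
        pairs = tree.query_pairs(mate_radius, output_type="ndarray")

        # local crowding: neighbours in a square window of half-width
        # 3 sigma_f (self excluded) divided by the window area clipped to the
        # habitat, so edge individuals see an unbiased density.  A uniform
        # window is used rather than a Gaussian kernel: a Gaussian peaks at
        # 1/(2 pi sigma_f^2) per neighbour, which exceeds K at small
        # sigma_f * K and makes family clumps self-extinguish.  With a
        # degenerate (sigma_f = 0) kernel fall back to the global density.
        if sig > 0:
            box = tree.query_pairs(radius, p=np.inf, output_type="ndarray")
            counts_nb = np.bincount(box.ravel(), minlength=n_cur).astype(float)
            area = ((np.minimum(px + radius, W) - np.maximum(px - radius, 0.0))
                    * (np.minimum(py + radius, W) - np.maximum(py - radius, 0.0)))
            density = counts_nb / area
        else:
            density = np.full(n_cur, n_cur / (W * W))
        lam = lam0 * K / (K + (lam0 - 1.0) * density)
        n_off = rng.poisson(lam)

        # one father per mother per generation: Gumbel-max over the Gaussian
        # mating kernel restricted to neighbours within the truncation radius
        # (only mothers that will actually reproduce are assigned a mate)
        father_of = np.full(n_cur, -1, dtype=np.int64)
        if len(pairs):
            mo = np.concatenate([pairs[:, 0], pairs[:, 1]])
            ca = np.concatenate([pairs[:, 1], pairs[:, 0]])
            live = n_off[mo] > 0
            mo, ca = mo[live], ca[live]
            if len(mo):
                if sig > 0:
                    dd2 = np.sum((pos[mo] - pos[ca]) ** 2, axis=1)
                    logw = -dd2 / (2 * sig * sig)
                else:
                    logw = np.zeros(len(mo))
                keys = logw + rng.gumbel(size=len(mo))
                gids, argm = _segment_argmax(keys, mo, n_cur)
                father_of[gids] = ca[argm]
        if sig == 0:
            # point-mass kernel: a mother with no co-located neighbour can
            # only mate at her own location, i.e. with herself
            father_of = np.where(father_of < 0, np.arange(n_cur), father_of)

        ok = (n_off > 0) & (father_of >= 0)
        mothers = np.repeat(np.nonzero(ok)[0], n_off[ok])
        if len(mothers) == 0:
            raise ExtinctionError(f"population extinct at generation {gen} of {T}")
        fathers = father_of[mothers]

        cx, cy = _disperse(px[mothers], py[mothers], sig, W, params.edge, rng)
        births.append(np.column_stack(
            [px[mothers], py[mothers], cx - px[mothers], cy - py[mothers]]
        ))

        t_child = float(T - gen)
        next_node = len(node_times)
        n_child = len(mothers)
        child_nodes = np.arange(n_child) * 2 + next_node
        _record_gametes(node_of[mothers], child_nodes, params.genome_length,
                        params.recomb_rate, rng, edge_buf)
        _record_gametes(node_of[fathers], child_nodes + 1, params.genome_length,
                        params.recomb_rate, rng, edge_buf)
        node_times.extend([t_child] * (2 * n_child))
        node_of = child_nodes
        px, py = cx, cy

    census = len(node_of)

    tables = tskit.TableCollection(sequence_length=params.genome_length)
    tables.time_units = "generations"
    tables.populations.add_row(metadata=b"")
    nt = np.asarray(node_times)
    n_nodes = len(nt)
    flags = np.zeros(n_nodes, dtype=np.uint32)
    sample_nodes = np.concatenate([node_of, node_of + 1])
    flags[sample_nodes] = tskit.NODE_IS_SAMPLE
    tables.nodes.set_columns(
        flags=flags, time=nt, population=np.zeros(n_nodes, dtype=np.int32)
    )
    eb = np.concatenate(edge_buf)
    tables.edges.set_columns(
        left=eb[:, 0], right=eb[:, 1],
        parent=eb[:, 2].astype(np.int32), child=eb[:, 3].astype(np.int32),
    )
    tables.sort()
    # order samples so individual i owns haplotypes (2i, 2i+1) after simplify
    order = np.empty(2 * census, dtype=np.int32)
    order[0::2] = node_of
    order[1::2] = node_of + 1
    tables.simplify(samples=order)
    ts = tables.tree_sequence()

    # close the remaining founder lineages with a coalescent history
    recap_seed = int(rng.integers(1, 2**31 - 1))
    pop_size = max(census, 2)
    rho = 4.0 * pop_size * params.recomb_rate * params.genome_length
    recap_rate = params.recomb_rate
    if params.recap_rho_cap and rho > params.recap_rho_cap:
        recap_rate = params.recap_rho_cap / (4.0 * pop_size * params.genome_length)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", msprime.TimeUnitsMismatchWarning)
        warnings.simplefilter("ignore", msprime.IncompletePopulationMetadataWarning)
        ts = msprime.sim_ancestry(
            initial_state=ts,
            recombination_rate=recap_rate,
            population_size=pop_size,
            random_seed=recap_seed,
        )
    mut_seed = int(rng.integers(1, 2**31 - 1))
    mts, rate_used = _overlay_mutations(ts, params, mut_seed)

    gm = _genotypes_from_ts(mts, census)
    ids = [str(i) for i in range(census)]
    loc = LocationsTable(sample_ids=ids, x=px.copy(), y=py.copy())
    return SimOutput(
        genotypes=gm,
        locations=loc,
        sigma_true=effective_sigma(sig),
        sigma_f=sig,
        params=params,
        mutation_rate_used=rate_used,
        census=census,
        births=np.concatenate(births) if births else None,
    )


def _genotypes_from_ts(mts: tskit.TreeSequence, n_ind: int) -> GenotypeMatrix:
    """Diploid derived-allele dosages at biallelic sites, minor-polarized."""
    hap = mts.genotype_matrix()  # sites x 2n, ancestral=0
    biallelic = (hap.max(axis=1) <= 1)
    hap = hap[biallelic]
    positions = mts.tables.sites.position[biallelic].astype(np.int64)
    # discrete-genome collisions at the same integer position are possible
    keep = np.concatenate([[True], np.diff(positions) > 0])
    hap = hap[keep]
    positions = positions[keep]
    dosage = hap.reshape(hap.shape[0], n_ind, 2).sum(axis=2).T  # n x sites
    counts, positions = polarize_minor(dosage, positions)
    return GenotypeMatrix(
        counts=counts.astype(np.int8),
        positions=positions,
        sample_ids=[str(i) for i in range(n_ind)],
        phased=False,
    )


def genotypes_from_tree_sequence(ts: tskit.TreeSequence) -> GenotypeMatrix:
    """Ingestion hook for externally simulated tree sequences.

    Accepts any tree sequence with diploid samples (haplotype nodes 2i and
    2i+1 belonging to individual i, mutations already present) and returns
    the minor-allele-count matrix over its biallelic sites.  This lets
    training data come from other continuous-space simulators that write
    tree sequences; sample locations must be supplied separately as a
    LocationsTable.
    """
    if ts.num_samples % 2 != 0:
        raise InvalidParameterError("expected an even number of haploid samples")
    return _genotypes_from_ts(ts, ts.num_samples // 2)


def polarize_minor(dosage: np.ndarray, positions: np.ndarray,
                   drop_monomorphic: bool = True):
    """Flip columns so the counted allele is the minor one; optionally drop
    columns monomorphic in this sample.  Ties at frequency 0.5 keep the
    original orientation."""
    dosage = np.asarray(dosage)
    n = dosage.shape[0]
    freq = dosage.sum(axis=0) / (2.0 * n)
    flip = freq > 0.5
    out = dosage.copy()
    out[:, flip] = 2 - out[:, flip]
    if drop_monomorphic:
        poly = (out.sum(axis=0) > 0)
        return out[:, poly], np.asarray(positions)[poly]
    return out, np.asarray(positions)


def sample_individuals(
    sim: SimOutput,
    n: int,
    scheme: str = "uniform",
    localities: LocationsTable | None = None,
    rng_seed: int = 0,
) -> SimOutput:
    """Take n individuals from a simulation, uniformly or nearest-to-localities.

    ``nearest-to-localities`` walks the localities in order, each claiming its
    closest not-yet-claimed simulated individual (Euclidean distance) — the
    scheme used to mirror an empirical sampling design.  Columns monomorphic
    in the subset are dropped and the minor allele re-polarized.
    """
    census = sim.genotypes.n
    if n > census:
        raise InsufficientIndividualsError(f"requested {n} of {census} individuals")
    if scheme == "uniform":
        rng = np.random.default_rng(rng_seed)
        idx = np.sort(rng.choice(census, size=n, replace=False))
    elif scheme == "nearest-to-localities":
        if localities is None:
            raise InvalidParameterError("nearest-to-localities requires localities")
        if localities.n != n:
            raise InvalidParameterError("need exactly n localities")
        coords = sim.locations.coords
        claimed = np.zeros(census, dtype=bool)
        idx_list = []
        for q in localities.coords:
            d2 = np.sum((coords - q) ** 2, axis=1)
            d2[claimed] = np.inf
            j = int(np.argmin(d2))
            claimed[j] = True
            idx_list.append(j)
        idx = np.asarray(idx_list)
    else:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")

    g = sim.genotypes
    counts, positions = polarize_minor(g.counts[idx].astype(np.int16), g.positions)
    gm = GenotypeMatrix(
        counts=counts.astype(np.int8),
        positions=positions,
        sample_ids=[g.sample_ids[i] for i in idx],
        phased=False,
    )
    return SimOutput(
        genotypes=gm,
        locations=sim.locations.subset(idx),
        sigma_true=sim.sigma_true,
        sigma_f=sim.sigma_f,
        params=sim.params,
        mutation_rate_used=sim.mutation_rate_used,
        census=sim.census,
        births=None,
    )


def generate_training_set(
    n_sims: int,
    draws_per_sim: int,
    n: int,
    m: int,
    params_template: SimParams,
    rng_seed: int,
    path=None,
    sigma_f_range: tuple[float, float] = (0.2, 3.0),
    progress: bool = False,
    retry_extinct: bool = True,
    min_mac: int = 2,
):
    """Simulate ``n_sims`` populations, sample each ``draws_per_sim`` times.

    Each draw takes n individuals uniformly at random, drops sites whose
    minor-allele count in the subset falls below ``min_mac`` (singletons are
    nearly uninformative about pairwise relatedness), and subsamples m SNP
    columns uniformly; the record is labelled with the simulation's true
    effective sigma.  Returns the DatasetStore written to ``path``.
    """
    from .io import filter_mac, subsample_snps

    if path is None:
        raise InvalidParameterError("generate_training_set requires an output path")
    rng = np.random.default_rng(rng_seed)
    records = []
    retries_left = 2 * n_sims if retry_extinct else 0
    for s in range(n_sims):
        while True:
            sf = draw_sigma_f(*sigma_f_range, rng_seed=int(rng.integers(2**31 - 1)))
            params = replace(
                params_template,
                sigma_f=sf,
                seed=int(rng.integers(2**31 - 1)),
                # headroom: a small sample loses low-frequency census
                # variants, and the MAC filter removes more
                min_snps=max(params_template.min_snps,
                             int((3.2 if min_mac >= 2 else 2.5) * m)),
            )
            try:
                sim = run_simulation(params)
                break
            except ExtinctionError:
                if retries_left <= 0:
                    raise
                retries_left -= 1
                logger.warning("simulation went extinct (sigma_f=%.3f); "
                               "redrawing parameters", sf)
        if progress:
            logger.info("sim %d/%d: sigma_f=%.3f census=%d snps=%d",
                        s + 1, n_sims, sf, sim.census, sim.genotypes.m)
        for _ in range(draws_per_sim):
            sub = sample_individuals(sim, n, "uniform",
                                     rng_seed=int(rng.integers(2**31 - 1)))
            g = filter_mac(sub.genotypes, min_mac)
            if g.m < m:
                raise InsufficientSNPsError(
                    f"simulation {s} yielded {g.m} SNPs in a sample "
                    f"(MAC >= {min_mac}), needed {m}"
                )
            g = subsample_snps(g, m, rng_seed=int(rng.integers(2**31 - 1)))
            records.append((g, sub.locations, sub.sigma_true, sub.sigma_f))
    return write_store(records, path)
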