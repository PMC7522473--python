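"""Seeded generators emulating the study's datasets at desk scale.

Every generator is a pure function of its :class:`GeneratorConfig`
(fixed seed => identical output) and returns a machine-readable truth
object alongside the data, so each pipeline stage has a planted-truth
recovery test. Defaults mirror the study conditions: an 83-species
panel with 16 rib-cluster carriers, a 500-nt 5'-UTR with the three
riboswitch elements and the seven mutant coordinates, triplicate qPCR,
duplicate RNA-seq with a 4-gene cluster induced ~18-fold, and logistic
growth at mu_max 0.31 h^-1 with riboflavin formation peaking at
13.9 ng mL^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import ScoringScheme
from .io_formats import Gene, GenomeRecord, MutantTableRow, load_mutant_table
from .kinetics_stats import TimeCourse
from .riboswitch import RiboswitchAnnotation, RiboswitchModel, scan_motifs

__all__ = [
    "GeneratorConfig",
    "RIB_QUERY_NAMES",
    "make_pangenome",
    "scatter_cluster",
    "make_riboswitch_set",
    "make_ct_table",
    "make_count_matrix",
    "make_timecourse",
    "make_fecal_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RIB_QUERY_NAMES = ("ribD", "ribE", "ribAB", "ribH", "ribCF", "ribU")

#: typical protein lengths (aa) for the six screened gene products;
#: compressed relative to the real enzymes to keep panels fast to align
QUERY_LENGTHS = {
    "ribD": 200,
    "ribE": 150,
    "ribAB": 220,
    "ribH": 140,
    "ribCF": 180,
    "ribU": 160,
}

#: housekeeping markers carried by every genome, used for the
#: housekeeping-vs-riboflavin tree comparison
HOUSEKEEPING_LENGTHS = {"rpoB": 240, "groEL": 210}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for all generators; every field is overridable.

    ``carrier_identity_range`` is the target protein percent-identity
    window (as fractions) planted into rib-cluster carriers;
    ``decoy_identity`` is the divergence of sub-threshold decoy genes
    given to some non-carriers. ``conservative_prob`` is the chance a
    planted substitution is drawn from the positive-scoring (BLOSUM62)
    residue pool, which keeps percent similarity above percent identity.
    """

    seed: int = 0
    # pangenome
    panel_size: int = 83
    n_carriers: int = 16
    carrier_identity_range: tuple[float, float] = (0.60, 0.95)
    universal_identity_range: tuple[float, float] = (0.45, 0.90)
    decoy_identity: float = 0.10
    decoy_fraction: float = 0.4
    conservative_prob: float = 0.5
    n_background_genes: int = 4
    background_length: int = 150
    carrier_layout: str = "contiguous"  # contiguous | split-contig | scattered
    # riboswitch
    utr_length: int = 500
    # qPCR
    ct_noise_sd: float = 0.15
    ct_reference_baseline: float = 20.0
    ct_target_baseline: float = 22.0
    # RNA-seq counts
    nb_dispersion: float = 0.05
    count_mean_range: tuple[float, float] = (100.0, 5000.0)
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    # fermentation
    growth_model: str = "logistic"  # logistic | exponential
    mu_max: float = 0.31
    od_initial: float = 0.05
    carrying_capacity: float = 3.0
    substrate_initial: float = 10.0
    biomass_yield: float | None = None  # OD units per g/L; default (K-X0)/S0
    product_peak_rate: float = 13.9
    product_beta: float = 0.0
    sampling_interval: float = 0.1
    t_end: float = 20.0
    od_noise_sd: float = 0.0
    # fecal donors
    fecal_range: tuple[float, float] = (80.7, 728.2)
    fecal_log_mean: float = np.log(250.0)
    fecal_log_sd: float = 0.55


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _positive_pools(scheme: ScoringScheme | None = None) -> dict[str, list[str]]:
    scheme = scheme or ScoringScheme()
    pools = {}
    for a in AMINO_ACIDS:
        pos = [b for b in AMINO_ACIDS if b != a and scheme.matrix[a, b] > 0]
        if not pos:  # e.g. cysteine has no positive off-diagonal partner
            pos = [b for b in AMINO_ACIDS if b != a and scheme.matrix[a, b] >= 0]
        pools[a] = pos or [b for b in AMINO_ACIDS if b != a]
    return pools


_POOLS = None


def mutate_protein(
    rng: np.random.Generator,
    protein: str,
    target_identity: float,
    conservative_prob: float = 0.5,
) -> str:
    """Substitute residues to hit a target fractional identity.

    Substituted residues are drawn from the positive-scoring BLOSUM62
    pool with probability ``conservative_prob`` (keeping similarity
    above identity), otherwise uniformly from the other residues.
    """
    global _POOLS
    if _POOLS is None:
        _POOLS = _positive_pools()
    if not 0 <= target_identity <= 1:
        raise ValueError("target identity must lie in [0, 1]")
    n_mut = round(len(protein) * (1.0 - target_identity))
    positions = rng.choice(len(protein), size=n_mut, replace=False)
    residues = list(protein)
    for pos in positions:
        orig = residues[pos]
        if rng.random() < conservative_prob:
            residues[pos] = rng.choice(_POOLS[orig])
        else:
            choices = [a for a in AMINO_ACIDS if a != orig]
            residues[pos] = rng.choice(choices)
    return "".join(residues)


def _assemble_genome(
    genome_id: str,
    species: str,
    niche: str,
    gene_entries: Sequence[tuple[str, str, str]],  # (locus, contig, protein)
) -> GenomeRecord:
    genes = []
    offsets: dict[str, int] = {}
    for locus, contig, protein in gene_entries:
        start = offsets.get(contig, 1)
        end = start + 3 * len(protein) - 1
        offsets[contig] = end + 200
        genes.append(
            Gene(
                locus_tag=locus,
                contig=contig,
                start=start,
                end=end,
                strand="+",
                protein=protein,
            )
        )
    return GenomeRecord(genome_id=genome_id, species=species, niche=niche, genes=genes)


def make_pangenome(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[GenomeRecord], pd.DataFrame, dict[str, str]]:
    """Simulate a genus-wide panel with a planted rib-cluster truth.

    Returns ``(panel, truth, queries)``. Carriers receive a contiguous
    ribDEABH block mutated to a per-genome target identity; a fraction
    of non-carriers receive heavily diverged decoy copies that must fail
    the homology filter; every genome carries ribCF/ribU homologs
    (conserved genus-wide) plus random background genes. ``truth`` has
    one row per genome: present, layout, niche, per-gene target
    identities.
    """
    if not 0 <= config.n_carriers <= config.panel_size:
        raise ValueError("n_carriers outside [0, panel_size]")
    if config.carrier_layout not in {"contiguous", "split-contig", "scattered"}:
        raise ValueError(f"unknown carrier layout {config.carrier_layout!r}")
    rng = np.random.default_rng(config.seed)
    queries = {name: _random_protein(rng, QUERY_LENGTHS[name]) for name in RIB_QUERY_NAMES}
    housekeeping = {
        name: _random_protein(rng, length)
        for name, length in HOUSEKEEPING_LENGTHS.items()
    }
    carrier_idx = set(
        rng.choice(config.panel_size, size=config.n_carriers, replace=False).tolist()
    )
    panel: list[GenomeRecord] = []
    truth_rows = []
    lo, hi = config.carrier_identity_range
    ulo, uhi = config.universal_identity_range
    for i in range(config.panel_size):
        gid = f"g{i + 1:03d}"
        species = f"B_species_{i + 1:03d}"
        is_carrier = i in carrier_idx
        if is_carrier:
            niche = "primate" if rng.random() < 14 / 16 else "human"
        else:
            niche = rng.choice(["human", "primate", "insect", "rodent"]).item()
        entries: list[tuple[str, str, str]] = []
        identities: dict[str, float] = {}
        background = [
            (f"{gid}_bg{j}", "c1", _random_protein(rng, config.background_length))
            for j in range(config.n_background_genes)
        ]
        rib_block: list[tuple[str, str, str]] = []
        if is_carrier:
            for name in ("ribD", "ribE", "ribAB", "ribH"):
                ident = float(rng.uniform(lo, hi))
                identities[name] = ident
                rib_block.append(
                    (
                        f"{gid}_{name}",
                        "c1",
                        mutate_protein(
                            rng, queries[name], ident, config.conservative_prob
                        ),
                    )
                )
        elif rng.random() < config.decoy_fraction:
            for name in ("ribD", "ribE", "ribAB", "ribH"):
                identities[name] = config.decoy_identity
                rib_block.append(
                    (
                        f"{gid}_{name}_decoy",
                        "c1",
                        mutate_protein(rng, queries[name], config.decoy_identity, 0.0),
                    )
                )
        universal = []
        for name in ("ribCF", "ribU"):
            ident = float(rng.uniform(ulo, uhi))
            identities[name] = ident
            universal.append(
                (
                    f"{gid}_{name}",
                    "c1",
                    mutate_protein(rng, queries[name], ident, config.conservative_prob),
                )
            )
        for name, ref in housekeeping.items():
            ident = float(rng.uniform(ulo, uhi))
            identities[name] = ident
            universal.append(
                (
                    f"{gid}_{name}",
                    "c1",
                    mutate_protein(rng, ref, ident, config.conservative_prob),
                )
            )
        layout = config.carrier_layout if is_carrier else "contiguous"
        if is_carrier and layout == "split-contig":
            rib_block = [(loc, "c2" if loc.endswith("ribD") else c, p) for loc, c, p in rib_block]
        elif is_carrier and layout == "scattered":
            rib_block = [
                (loc, f"c{j + 2}", p) for j, (loc, c, p) in enumerate(rib_block)
            ]
        # keep the (possibly decoy) block contiguous in annotation order,
        # flanked by background genes
        half = len(background) // 2
        entries = background[:half] + rib_block + universal + background[half:]
        panel.append(_assemble_genome(gid, species, niche, entries))
        truth_rows.append(
            {
                "genome_id": gid,
                "species": species,
                "niche": niche,
                "present": is_carrier,
                "layout": layout,
                **{f"identity_{k}": v for k, v in identities.items()},
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("genome_id")
    return panel, truth, queries


def scatter_cluster(genome: GenomeRecord) -> GenomeRecord:
    """Move each rib-block gene to its own contig, sequences unchanged.

    Used by the co-location property tests: a carrier whose cluster is
    scattered must always flip to an absent call.
    """
    new_genes = []
    j = 0
    for gene in genome.genes:
        base = gene.locus_tag.rsplit("_", 1)[-1]
        if base in {"ribD", "ribE", "ribAB", "ribH"}:
            j += 1
            new_genes.append(
                Gene(
                    locus_tag=gene.locus_tag,
                    contig=f"scatter{j}",
                    start=gene.start,
                    end=gene.end,
                    strand=gene.strand,
                    protein=gene.protein,
                )
            )
        else:
            new_genes.append(gene)
    return GenomeRecord(
        genome_id=genome.genome_id,
        species=genome.species,
        niche=genome.niche,
        genes=new_genes,
        contigs=dict(genome.contigs),
    )


# required wild-type bases at the mutant-table coordinates, and the
# riboswitch element placements that put position 105 (and 102) inside
# an anti-antiterminator span
_ANTI_ANTIT_1_START = 70  # CATCTTC at 70..76
_ANTI_ANTIT_2_START = 102  # GAAGATG at 102..108
_ANTIT_START = 130  # TTCAGGGC at 130..137


def make_riboswitch_set(
    config: GeneratorConfig = GeneratorConfig(),
) -> dict:
    """Build the WT riboswitch UTR plus the seven point-mutant variants.

    The WT sequence carries the antiterminator and both
    anti-antiterminator motifs at fixed positions, and matches the
    mutant table's WT base at every mutated coordinate; each variant
    differs from WT at exactly its table position. Returns a dict with
    keys ``wt``, ``variants`` (mutant id -> sequence), ``annotation``,
    ``table`` and ``model``.
    """
    if config.utr_length < _ANTIT_START + 8:
        raise ValueError("UTR too short to place the riboswitch elements")
    rng = np.random.default_rng(config.seed)
    model = RiboswitchModel(utr_length=config.utr_length)
    seq = list(rng.choice(list("ACGT"), size=config.utr_length))
    placements = [
        (_ANTI_ANTIT_1_START, model.anti_antiterminators[0]),
        (_ANTI_ANTIT_2_START, model.anti_antiterminators[1]),
        (_ANTIT_START, model.antiterminator),
    ]
    for start, motif in placements:
        seq[start - 1 : start - 1 + len(motif)] = list(motif)
    table = load_mutant_table()
    for row in table:
        if row.position is None:
            continue
        covered = any(
            s <= row.position <= s + len(m) - 1 for s, m in placements
        )
        current = seq[row.position - 1]
        if covered and current != row.wt_base:
            raise RuntimeError(
                f"motif placement conflicts with required WT base at {row.position}"
            )
        seq[row.position - 1] = row.wt_base
    wt = "".join(seq)
    variants = {}
    for row in table:
        if row.position is None:
            continue
        var = list(wt)
        var[row.position - 1] = row.mut_base
        variants[row.mutant_id] = "".join(var)
    annotation = RiboswitchAnnotation(utr=wt, motif_hits=scan_motifs(wt, model))
    return {
        "wt": wt,
        "variants": variants,
        "annotation": annotation,
        "table": table,
        "model": model,
    }


def make_ct_table(
    config: GeneratorConfig = GeneratorConfig(),
    target_fold: float = 15.0,
    n_replicates: int = 3,
    target_gene: str = "ribD",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with an injected target fold change.

    Reference-gene Cts scatter around a shared baseline; the mutant
    group's target Ct is shifted by -log2(fold); Gaussian cycle noise
    of ``ct_noise_sd`` is added to every measurement.
    """
    if target_fold <= 0:
        raise ValueError("target_fold must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    genes = {"groEL": config.ct_reference_baseline, "gyrA": config.ct_reference_baseline}
    for group, shift in (("WT", 0.0), ("mutant", -np.log2(target_fold))):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for gene, base in genes.items():
                rows.append(
                    (
                        sample,
                        group,
                        gene,
                        base + rng.normal(0.0, config.ct_noise_sd),
                    )
                )
            rows.append(
                (
                    sample,
                    group,
                    target_gene,
                    config.ct_target_baseline
                    + shift
                    + rng.normal(0.0, config.ct_noise_sd),
                )
            )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


def make_count_matrix(
    config: GeneratorConfig = GeneratorConfig(),
    de_gene_set: Sequence[str] = ("rib_1", "rib_2", "rib_3", "rib_4"),
    fold: float = 18.0,
    n_genes: int = 200,
    n_per_group: int = 2,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Simulate an RNA-seq count matrix with a planted DE gene set.

    Counts are negative-binomial with gene means drawn log-uniformly
    from ``count_mean_range`` and common dispersion ``nb_dispersion``;
    mutant-group means are multiplied by ``fold`` for the DE genes, and
    per-sample size-factor perturbations are applied. Returns
    ``(counts, groups, truth)``.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if config.nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if len(de_gene_set) > n_genes:
        raise ValueError("de_gene_set larger than the number of generated genes")
    rng = np.random.default_rng(config.seed)
    gene_names = list(de_gene_set) + [
        f"gene_{i + 1}" for i in range(n_genes - len(de_gene_set))
    ]
    lo, hi = config.count_mean_range
    base_means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    samples = [f"WT_{i + 1}" for i in range(n_per_group)] + [
        f"mutant_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["WT"] * n_per_group + ["mutant"] * n_per_group, index=samples
    )
    sf_true = rng.uniform(*config.size_factor_range, size=len(samples))
    de_mask = np.isin(gene_names, list(de_gene_set))
    counts = np.zeros((n_genes, len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        mu = base_means * sf_true[j]
        if groups[sample] == "mutant":
            mu = np.where(de_mask, mu * fold, mu)
        if config.nb_dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / config.nb_dispersion
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(counts, index=gene_names, columns=samples)
    truth = {
        "de_genes": list(de_gene_set),
        "fold": fold,
        "dispersion": config.nb_dispersion,
        "size_factors": dict(zip(samples, sf_true.tolist())),
    }
    return df, groups, truth


def make_timecourse(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[TimeCourse, dict]:
    """Simulate a pH-controlled batch fermentation time course.

    Biomass follows a logistic curve (or a pure exponential when
    ``growth_model='exponential'``); substrate is consumed with a fixed
    biomass yield and the culture goes stationary at exhaustion;
    riboflavin follows Luedeking-Piret formation dP/dt = alpha dX/dt +
    beta X, with alpha set so the analytic peak rate equals
    ``product_peak_rate``. Returns ``(timecourse, truth)``.
    """
    if config.mu_max <= 0:
        raise ValueError("mu_max must be positive")
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.t_end + 1e-9, config.sampling_interval)
    x0, k, mu = config.od_initial, config.carrying_capacity, config.mu_max
    if config.growth_model == "exponential":
        x = x0 * np.exp(mu * t)
        dxdt = mu * x
        alpha = config.product_peak_rate / (mu * x[-1])  # peak at t_end
        peak_rate = config.product_peak_rate
    elif config.growth_model == "logistic":
        x = k * x0 * np.exp(mu * t) / (k + x0 * (np.exp(mu * t) - 1.0))
        dxdt = mu * x * (1.0 - x / k)
        # logistic dX/dt peaks at mu*K/4 (inflection, X = K/2)
        alpha = config.product_peak_rate / (mu * k / 4.0)
        peak_rate = config.product_peak_rate
    else:
        raise ValueError(f"unknown growth model {config.growth_model!r}")
    yield_ = (
        config.biomass_yield
        if config.biomass_yield is not None
        else (k - x0) / config.substrate_initial
    )
    if yield_ <= 0:
        raise ValueError("biomass yield must be positive")
    x_cap = x0 + yield_ * config.substrate_initial
    x = np.minimum(x, x_cap)
    substrate = np.maximum(config.substrate_initial - (x - x0) / yield_, 0.0)
    if config.product_beta:
        # integrate the beta*X term on the sampled grid
        beta_term = np.concatenate(
            [[0.0], np.cumsum(0.5 * (x[1:] + x[:-1]) * np.diff(t))]
        )
    else:
        beta_term = np.zeros_like(t)
    product = alpha * (x - x0) + config.product_beta * beta_term
    acetate = 1.2 * (config.substrate_initial - substrate)
    lactate = 0.8 * (config.substrate_initial - substrate)
    od = x + rng.normal(0.0, config.od_noise_sd, size=x.size)
    data = pd.DataFrame(
        {
            "time": t,
            "od600": np.maximum(od, 1e-6),
            "lactose": substrate,
            "riboflavin": product,
            "acetate": acetate,
            "lactate": lactate,
        }
    )
    truth = {
        "mu_max": mu,
        "max_production_rate": peak_rate,
        "carrying_capacity": k,
        "yield": yield_,
        "model": config.growth_model,
    }
    return TimeCourse(data), truth


def make_fecal_table(
    config: GeneratorConfig = GeneratorConfig(), n_donors: int = 10
) -> pd.DataFrame:
    """Donor fecal riboflavin concentrations (ng per g wet weight).

    Values follow a right-skewed log-normal shape truncated by
    rejection to ``fecal_range``.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.fecal_range
    values = []
    while len(values) < n_donors:
        draw = float(rng.lognormal(config.fecal_log_mean, config.fecal_log_sd))
        if lo <= draw <= hi:
            values.append(draw)
    return pd.DataFrame(
        {
            "donor": [f"donor_{i + 1:02d}" for i in range(n_donors)],
            "riboflavin_ng_per_g": values,
        }
    )
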