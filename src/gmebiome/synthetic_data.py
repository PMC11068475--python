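"""Seeded toy data generator for the cross-inoculation study design.

The experiment crosses nine *Lotus* accessions (G) with four soil-microbiome
inoculants (M: two field extracts, their mixture, and a noninoculated
control) under two growth environments (E: salt / control), two pots per
combination and six plants per pot.  This module generates, at a chosen
scale, every input the downstream pipeline consumes:

* a synthetic 16S reference collection with a lineage hierarchy, an
  accepted-names list, and a host-genome decoy;
* per-sample "true" community compositions driven by log-linear G/M/E
  factor effects;
* paired-end UMI-tagged FASTQ reads with PCR duplication and substitution
  errors, plus a molecule-level truth log;
* gamma-distributed plant phenotypes (SL, RL, NOL, NOB) with pot random
  intercepts and a shared latent vigor term inducing positive correlation.

All outputs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "CommunityModel",
    "ReadSimConfig",
    "PhenoModel",
    "generate_reference",
    "simulate_communities",
    "simulate_reads",
    "simulate_phenotypes",
    "default_community_model",
    "default_pheno_model",
    "TERMS",
]

# Factorial terms in the order used throughout the pipeline.
TERMS = ("G", "M", "E", "GxM", "GxE", "MxE", "GxMxE")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

_DEFAULT_GENOTYPES = (
    "Gifu", "MG11", "MG20", "MG46", "MG56", "MG63", "MG67", "MG68", "Burttii",
)


@dataclass(frozen=True)
class StudyDesign:
    """Factor levels and replication of the cross-inoculation experiment."""

    genotypes: tuple[str, ...] = _DEFAULT_GENOTYPES
    inoculants: tuple[str, ...] = ("F5C", "F5S", "MIX", "NONE")
    environments: tuple[str, ...] = ("SALT", "CONTROL")
    pots_per_combination: int = 2
    plants_per_pot: int = 6

    def __post_init__(self):
        for name in ("genotypes", "inoculants", "environments"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name} contains duplicate labels")
        if self.pots_per_combination < 1 or self.plants_per_pot < 1:
            raise ValueError("replication counts must be positive")

    @property
    def n_combinations(self) -> int:
        return len(self.genotypes) * len(self.inoculants) * len(self.environments)

    @property
    def n_pots(self) -> int:
        return self.n_combinations * self.pots_per_combination

    def combinations(self):
        return itertools.product(self.genotypes, self.inoculants, self.environments)

    def term_df(self, terms=TERMS) -> dict[str, int]:
        """Degrees of freedom per factorial term for this design's levels."""
        sizes = {
            "G": len(self.genotypes),
            "M": len(self.inoculants),
            "E": len(self.environments),
        }
        out = {}
        for term in terms:
            df = 1
            for f in term.split("x"):
                df *= sizes[f] - 1
            out[term] = df
        return out


@dataclass
class CommunityModel:
    """Log-linear factor-effect model for per-sample taxon proportions.

    ``effect_scales`` are log-scale standard deviations of planted factor
    effects; the default calibration makes M and E the dominant drivers and
    G plus all interactions minor, so the downstream variance partition is
    dominated by inoculant and environment.
    """

    n_taxa: int
    baseline_logabundance: np.ndarray
    effect_scales: dict[str, float]
    overdispersion: float = 0.30
    host_fraction: float = 0.0

    def __post_init__(self):
        self.baseline_logabundance = np.asarray(self.baseline_logabundance, float)
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.baseline_logabundance.shape != (self.n_taxa,):
            raise ValueError("baseline_logabundance must have length n_taxa")
        if set(self.effect_scales) != set(TERMS):
            raise ValueError(f"effect_scales keys must be exactly {TERMS}")
        if any(v < 0 for v in self.effect_scales.values()):
            raise ValueError("effect scales must be non-negative")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if not (0 <= self.host_fraction < 1):
            raise ValueError("host_fraction must lie in [0, 1)")


def default_community_model(n_taxa: int = 60, seed: int = 0,
                            host_fraction: float = 0.0) -> CommunityModel:
    """Default calibration: M and E large, G and interactions small.

    Scales chosen so the community variance partition under the default
    design mirrors the study's pattern: inoculant and environment each
    explain ~20-35% of Morisita-Horn beta diversity, genotype and every
    interaction a few percent, with a ~25-35% residual from per-sample
    overdispersion.  The environment scale exceeds the inoculant scale
    because E has fewer levels (its between-level variance enters with one
    degree of freedom where M has two).
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 0.5, n_taxa)
    scales = {
        "G": 0.08, "M": 0.32, "E": 0.45,
        "GxM": 0.11, "GxE": 0.13, "MxE": 0.22, "GxMxE": 0.12,
    }
    return CommunityModel(n_taxa=n_taxa, baseline_logabundance=baseline,
                          effect_scales=scales, overdispersion=0.55,
                          host_fraction=host_fraction)


@dataclass
class ReadSimConfig:
    """Layout and error model for UMI-tagged paired-end amplicon reads."""

    umi_length: int = 12
    umi_pattern: str = "NNNHNNNWNNNH"
    # 3' segments of the two-step PCR primers: 16S universal sequences.
    fwd_universal: str = "AACMGGATTAGATACCCKG"
    rev_universal: str = "ACGTCATCCCCACCTTCC"
    mean_pcr_duplicates: float = 1.0
    per_base_error: float = 0.0
    reads_per_sample: int = 200
    read_length: int = 230
    seed: int = 0

    def __post_init__(self):
        if len(self.umi_pattern) != self.umi_length:
            raise ValueError("umi_pattern length must equal umi_length")
        if not (0 <= self.per_base_error <= 1):
            raise ValueError("per_base_error must be a probability")
        if self.mean_pcr_duplicates < 0:
            raise ValueError("mean_pcr_duplicates must be non-negative")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be positive")


@dataclass
class PhenoModel:
    """Gamma phenotype model with log-scale factor effects.

    ``genotype_means`` are mean shoot lengths (mm) per accession;
    ``factor_effects`` maps each non-G term to log-scale effects per level
    (or level tuple for interactions).  ``vigor_sd`` is the latent
    per-individual term shared across traits, which induces the all-positive
    phenotype correlations; ``pot_sd`` the pot random intercept.
    """

    genotype_means: dict[str, float]
    factor_effects: dict[str, dict]
    pot_sd: float = 0.12
    vigor_sd: float = 0.15
    gamma_shape: float = 12.0
    death_rate: float = 0.09
    # multiplier applied to M and GxM effects for the root-length trait
    rl_m_scale: float = 2.5
    rl_gxm_scale: float = 1.5

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if any(m <= 0 for m in self.genotype_means.values()):
            raise ValueError("genotype means must be positive")
        if not (0 <= self.death_rate < 1):
            raise ValueError("death_rate must be a probability below 1")
        if self.pot_sd < 0 or self.vigor_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def default_pheno_model(design: StudyDesign | None = None) -> PhenoModel:
    """Default calibration mirroring the phenotype effect-size pattern.

    Genotype means span a wide log-scale range (large G effect); the
    environment effect is moderate with salt positive for growth in this
    system; inoculant main effects are small while genotype-by-inoculant
    effects are several-fold larger in variance, reproducing the
    G x M > M contrast.  Interaction effects are drawn once from a fixed
    internal stream so the defaults are deterministic constants.
    """
    design = design or StudyDesign()
    g = list(design.genotypes)
    m = list(design.inoculants)
    e = list(design.environments)
    means = dict(zip(g, 10.0 * np.exp(np.linspace(-0.35, 0.35, len(g)))))

    rng = np.random.default_rng(20240427)  # fixed: defaults are constants
    m_eff = dict(zip(m, [-0.05, 0.04, 0.0, 0.08][: len(m)]))
    if len(m) > 4:
        for extra in m[4:]:
            m_eff[extra] = 0.0
    e_eff = {lvl: val for lvl, val in zip(e, [0.12, -0.12])}
    if len(e) > 2:
        for extra in e[2:]:
            e_eff[extra] = 0.0
    gxm = {pair: rng.normal(0.0, 0.09) for pair in itertools.product(g, m)}
    gxe = {pair: rng.normal(0.0, 0.05) for pair in itertools.product(g, e)}
    mxe = {pair: rng.normal(0.0, 0.01) for pair in itertools.product(m, e)}
    gxmxe = {trip: rng.normal(0.0, 0.03)
             for trip in itertools.product(g, m, e)}
    effects = {"M": m_eff, "E": e_eff, "GxM": gxm, "GxE": gxe,
               "MxE": mxe, "GxMxE": gxmxe}
    return PhenoModel(genotype_means=means, factor_effects=effects)


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------

_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def generate_reference(n_taxa: int, lineage_depth: int = 6, seed: int = 0,
                       withheld_fraction: float = 0.1,
                       target_length: int = 320,
                       n_host: int = 3, outdir: str | Path | None = None):
    """Generate a synthetic 16S reference set, lineage table, accepted-names
    list and host-genome decoy.

    Reference sequences are independent random DNA, so pairwise identity is
    ~25% and top-hit assignment of error-free reads is unambiguous.  A
    ``withheld_fraction`` of lineage names (rounded to the nearest count, at
    the deepest ranks first) is left off the accepted-names list to exercise
    the NotAssigned rule.

    Returns a dict with keys ``reference`` (id -> sequence), ``lineage``
    (DataFrame), ``accepted_names`` (DataFrame rank/name), ``host``
    (id -> sequence) and, if ``outdir`` is given, writes reference.fasta,
    lineage.tsv, accepted_names.tsv and host.fasta there.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    if not (0 <= withheld_fraction < 1):
        raise ValueError("withheld_fraction must lie in [0, 1)")
    ranks = _RANKS[:lineage_depth]
    rng = np.random.default_rng(seed)

    reference = {f"R{i + 1:04d}": _random_seq(rng, target_length)
                 for i in range(n_taxa)}

    # Lineage hierarchy: coarse ranks shared among taxa, genus unique.
    lineage_rows = []
    for i, rid in enumerate(reference):
        row = {"reference_id": rid}
        for d, rank in enumerate(ranks):
            if rank == "domain":
                row[rank] = "Bacteria"
            elif rank == "genus":
                row[rank] = f"Genus{i + 1:03d}"
            else:
                width = max(1, 2 ** d)  # coarser ranks have fewer names
                row[rank] = f"{rank.capitalize()}{(i % width) + 1:02d}"
        lineage_rows.append(row)
    lineage = pd.DataFrame(lineage_rows)

    all_names = [(rank, name)
                 for rank in ranks if rank != "domain"
                 for name in sorted(lineage[rank].unique())]
    all_names = [("domain", "Bacteria")] + all_names
    # withhold a fraction of the deepest-rank (per-taxon) names to exercise
    # the NotAssigned rule: round(withheld_fraction * n_taxa) genus names
    deepest = ranks[-1]
    deep_names = sorted(lineage[deepest].unique())
    n_withhold = int(round(withheld_fraction * n_taxa))
    chosen = rng.choice(len(deep_names), size=min(n_withhold, len(deep_names)),
                        replace=False)
    withheld = {(deepest, deep_names[i]) for i in chosen}
    accepted = pd.DataFrame(
        [{"rank": r, "name": n} for r, n in all_names if (r, n) not in withheld]
    )

    host = {f"HOST{j + 1:02d}": _random_seq(rng, target_length)
            for j in range(n_host)}

    out = {"reference": reference, "lineage": lineage,
           "accepted_names": accepted, "host": host,
           "withheld": sorted(withheld)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "reference.fasta", reference)
        _write_fasta(outdir / "host.fasta", host)
        lineage.to_csv(outdir / "lineage.tsv", sep="\t", index=False)
        accepted.to_csv(outdir / "accepted_names.tsv", sep="\t", index=False)
    return out


def _write_fasta(path: Path, records: dict[str, str]):
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n{seq}\n")


# --------------------------------------------------------------------------
# community simulation
# --------------------------------------------------------------------------

def simulate_communities(design: StudyDesign, model: CommunityModel,
                         seed: int = 0, samples_per_pot: int = 3,
                         taxa: list[str] | None = None):
    """Simulate per-sample true taxon compositions plus sample metadata.

    Each sampled plant's community is softmax of baseline log-abundance plus
    additive factor effects (per planted term) plus i.i.d. overdispersion
    noise.  Returns ``(composition, metadata)`` where composition is a
    samples x taxa DataFrame of proportions summing to 1 per row.
    """
    if samples_per_pot < 1:
        raise ValueError("samples_per_pot must be positive")
    taxa = list(taxa) if taxa is not None else [
        f"R{i + 1:04d}" for i in range(model.n_taxa)]
    if len(taxa) != model.n_taxa:
        raise ValueError("taxa labels must match model.n_taxa")

    rng = np.random.default_rng(seed)
    scales = model.effect_scales
    eff = {
        "G": {g: rng.normal(0, scales["G"], model.n_taxa) for g in design.genotypes},
        "M": {m: rng.normal(0, scales["M"], model.n_taxa) for m in design.inoculants},
        "E": {e: rng.normal(0, scales["E"], model.n_taxa) for e in design.environments},
        "GxM": {p: rng.normal(0, scales["GxM"], model.n_taxa)
                for p in itertools.product(design.genotypes, design.inoculants)},
        "GxE": {p: rng.normal(0, scales["GxE"], model.n_taxa)
                for p in itertools.product(design.genotypes, design.environments)},
        "MxE": {p: rng.normal(0, scales["MxE"], model.n_taxa)
                for p in itertools.product(design.inoculants, design.environments)},
        "GxMxE": {t: rng.normal(0, scales["GxMxE"], model.n_taxa)
                  for t in itertools.product(design.genotypes, design.inoculants,
                                             design.environments)},
    }

    rows, meta = [], []
    for g, m, e in design.combinations():
        mu = (model.baseline_logabundance
              + eff["G"][g] + eff["M"][m] + eff["E"][e]
              + eff["GxM"][(g, m)] + eff["GxE"][(g, e)] + eff["MxE"][(m, e)]
              + eff["GxMxE"][(g, m, e)])
        for pot in range(design.pots_per_combination):
            pot_id = f"{g}.{m}.{e}.p{pot + 1}"
            for rep in range(samples_per_pot):
                logab = mu + rng.normal(0, model.overdispersion, model.n_taxa)
                p = np.exp(logab - logab.max())
                rows.append(p / p.sum())
                meta.append({"sample": f"{pot_id}.s{rep + 1}",
                             "G": g, "M": m, "E": e, "pot": pot_id})
    metadata = pd.DataFrame(meta)
    composition = pd.DataFrame(rows, index=metadata["sample"].to_numpy(),
                               columns=taxa)
    return composition, metadata


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def _draw_umi(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(composition: pd.DataFrame, reference: dict[str, str],
                   config: ReadSimConfig, outdir: str | Path,
                   host: dict[str, str] | None = None,
                   host_fraction: float = 0.0):
    """Emit paired FASTQ files for every sample in ``composition``.

    Each biological molecule receives a fresh UMI drawn from the configured
    IUPAC pattern and is emitted ``1 + Poisson(mean_pcr_duplicates)`` times
    (duplicates share the UMI; every emitted copy gets independent
    substitution errors).  The forward read starts at the UMI, followed by
    the forward universal primer and the target; the reverse read covers the
    amplicon 3' end so pairs overlap.  Returns (r1_path, r2_path, log) where
    ``log`` records molecule-level truth per sample for oracle checks.
    """
    if composition.shape[1] == 0 or composition.shape[0] == 0:
        raise ValueError("composition must be non-empty")
    missing = set(composition.columns) - set(reference)
    if missing:
        raise ValueError(f"composition taxa missing from reference: {missing}")
    if host_fraction and not host:
        raise ValueError("host_fraction > 0 requires host sequences")

    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1_path, r2_path = outdir / "reads_R1.fastq", outdir / "reads_R2.fastq"
    log: dict = {"samples": {}}
    host_ids = list(host) if host else []

    rc_rev_universal = revcomp(config.rev_universal)
    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        ridx = 0
        for sample in composition.index:
            probs = composition.loc[sample].to_numpy(float)
            probs = probs / probs.sum()
            n_mol = config.reads_per_sample
            n_host = rng.binomial(n_mol, host_fraction) if host_fraction else 0
            counts = rng.multinomial(n_mol - n_host, probs)
            sources = [t for t, c in zip(composition.columns, counts)
                       for _ in range(c)]
            if n_host:
                sources += [host_ids[rng.integers(0, len(host_ids))]
                            for _ in range(n_host)]
            mol_log = []
            for taxon in sources:
                umi = _draw_umi(rng, config.umi_pattern)
                target = reference[taxon] if taxon in reference else host[taxon]
                amplicon = (umi + config.fwd_universal + target
                            + rc_rev_universal)
                n_copies = 1 + rng.poisson(config.mean_pcr_duplicates)
                mol_log.append({"taxon": taxon, "umi": umi, "copies": int(n_copies)})
                L = min(config.read_length, len(amplicon))
                for _ in range(n_copies):
                    fwd = _mutate(rng, amplicon[:L], config.per_base_error)
                    rev = _mutate(rng, revcomp(amplicon[-L:]),
                                  config.per_base_error)
                    qual = "I" * L
                    ridx += 1
                    name = f"@{sample}:{ridx}"
                    r1.write(f"{name}/1\n{fwd}\n+\n{qual}\n")
                    r2.write(f"{name}/2\n{rev}\n+\n{qual}\n")
            log["samples"][str(sample)] = {
                "molecules": mol_log,
                "molecule_counts": _tally(m["taxon"] for m in mol_log),
            }
    with open(outdir / "simulation_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return r1_path, r2_path, log


def _tally(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return out


# --------------------------------------------------------------------------
# phenotype simulation
# --------------------------------------------------------------------------

def simulate_phenotypes(design: StudyDesign, model: PhenoModel,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate the per-individual phenotype table (SL, RL, NOL, NOB).

    SL is gamma with log-mean = log genotype mean + factor effects + pot
    intercept + latent vigor; RL shares the structure with rescaled M and
    GxM effects; NOL and NOB are rounded positive transforms driven by the
    same vigor, so all four traits are positively correlated.  A
    ``death_rate`` fraction of individuals is dropped.
    """
    for g in design.genotypes:
        if g not in model.genotype_means:
            raise ValueError(f"genotype {g!r} missing from genotype_means")
    rng = np.random.default_rng(seed)
    fe = model.factor_effects

    def effect(term, key):
        return fe.get(term, {}).get(key, 0.0)

    rows = []
    idx = 0
    for g, m, e in design.combinations():
        base = (np.log(model.genotype_means[g])
                + effect("M", m) + effect("E", e)
                + effect("GxM", (g, m)) + effect("GxE", (g, e))
                + effect("MxE", (m, e)) + effect("GxMxE", (g, m, e)))
        rl_base = (np.log(model.genotype_means[g]) - np.log(1.6)
                   + model.rl_m_scale * effect("M", m) + 0.6 * effect("E", e)
                   + model.rl_gxm_scale * effect("GxM", (g, m))
                   + effect("GxE", (g, e)) + effect("MxE", (m, e))
                   + effect("GxMxE", (g, m, e)))
        for pot in range(design.pots_per_combination):
            pot_id = f"{g}.{m}.{e}.p{pot + 1}"
            pot_dev = rng.normal(0, model.pot_sd)
            for plant in range(design.plants_per_pot):
                idx += 1
                vigor = rng.normal(0, model.vigor_sd)
                k = model.gamma_shape
                sl_mu = np.exp(base + pot_dev + vigor)
                rl_mu = np.exp(rl_base + pot_dev + vigor)
                sl = rng.gamma(k, sl_mu / k)
                rl = rng.gamma(k, rl_mu / k)
                nol = max(1, int(round(rng.gamma(k, (4.0 * np.exp(vigor + 0.3 * pot_dev)) / k))))
                nob = max(1, int(round(rng.gamma(k, (2.0 * np.exp(vigor + 0.3 * pot_dev)) / k))))
                rows.append({"individual": f"ind{idx:04d}", "G": g, "M": m,
                             "E": e, "pot": pot_id, "SL": sl, "RL": rl,
                             "NOL": nol, "NOB": nob})
    table = pd.DataFrame(rows)
    if model.death_rate > 0:
        alive = rng.random(len(table)) >= model.death_rate
        table = table.loc[alive].reset_index(drop=True)
    return table
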