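"""Synthetic successional-community generator with exported ground truth.

Emulates the statistical structure of a root-associated microbiome survey
over a growing season: four compartments on a soil→root spatial gradient,
weekly time points over ~140 days, two field sites with site-specific
early-season taxa, genotypes that develop at different rates, and an
optional drought arm that inflates early-colonizer and deflates
late-colonizer abundance inside the root.

The data-generating model, per OTU and sample::

    log a = baseline + affinity[position] + curve(dev_time)

where ``dev_time = age_days × development_rate`` is developmental time,
and ``curve`` is an archetype-specific succession curve: early colonizers
follow a falling logistic, late colonizers a rising logistic, complex
taxa a Gaussian bump, and static taxa a constant.  Site-specific OTUs are
absent (zero) outside their home site.  Compositions are renormalized to
the simplex, optionally drought-perturbed, and sampled as
Dirichlet-multinomial counts to produce realistic overdispersion.

Default succession midpoints are drawn around the developmental time
where the 1–27 stage scale reaches 18 (panicle initiation), i.e.
140·17/26 ≈ 91.5 developmental days, with a wide spread (sd 25 d) so
turnover is staggered across the season while the aggregate early→late
switch still tracks entry into reproductive growth for every genotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    COMPARTMENT_POSITIONS, OtuTable, RAW_COUNTS, TaxonomyTable, RANKS,
    validate_metadata, write_metadata, write_otu_table, write_taxonomy,
)

ARCHETYPES = ("early", "late", "complex", "static")

#: developmental day at which stage(t) = 1 + 26·t/140 reaches 18
STAGE18_DEV_DAY = 140.0 * 17.0 / 26.0

_PHYLUM_POOL = {
    "early": [("Proteobacteria", "Betaproteobacteria"),
              ("Proteobacteria", "Gammaproteobacteria"),
              ("Bacteroidetes", "unassigned"),
              ("Firmicutes", "unassigned")],
    "late": [("Proteobacteria", "Deltaproteobacteria"),
             ("Proteobacteria", "Alphaproteobacteria"),
             ("Chloroflexi", "unassigned"),
             ("Acidobacteria", "unassigned"),
             ("Spirochaetes", "unassigned")],
    "complex": [("Verrucomicrobia", "unassigned"),
                ("Gemmatimonadetes", "unassigned")],
    "static": [("Actinobacteria", "unassigned"),
               ("Nitrospirae", "unassigned"),
               ("Planctomycetes", "unassigned"),
               ("Euryarchaeota", "unassigned")],
}


@dataclass
class SimulationDesign:
    """Factorial layout of a simulated growing season."""

    sites: tuple = ("site_A", "site_B")
    compartments: tuple = ("bulk_soil", "rhizosphere", "rhizoplane",
                           "endosphere")
    timepoints_days: tuple = tuple(range(7, 141, 7))
    replicates_per_cell: int = 3
    genotypes: dict = field(default_factory=lambda: {"M206": 1.0})
    drought_arms: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites or not self.compartments or not self.timepoints_days:
            raise ValueError("empty factor list in simulation design")
        if not self.genotypes:
            raise ValueError("at least one genotype required")
        if any(r <= 0 for r in self.genotypes.values()):
            raise ValueError("development rates must be positive")


def developmental_stage(age_days, development_rate) -> np.ndarray:
    """Map plant age to the 1–27 stage scale at a genotype's rate."""
    stage = np.round(1.0 + np.asarray(development_rate, dtype=float)
                     * 26.0 * np.asarray(age_days, dtype=float) / 140.0)
    return np.clip(stage, 1, 27).astype(int)


def build_design(design: SimulationDesign) -> pd.DataFrame:
    """Expand a design into one metadata record per sample."""
    treatments = (["well_watered", "drought"] if design.drought_arms
                  else ["none"])
    rows = []
    for site in design.sites:
        for comp in design.compartments:
            for t in design.timepoints_days:
                for geno, rate in design.genotypes.items():
                    for trt in treatments:
                        for rep in range(design.replicates_per_cell):
                            rows.append({
                                "site": site,
                                "season": "2016",
                                "compartment": comp,
                                "position": COMPARTMENT_POSITIONS[comp],
                                "age_days": float(t),
                                "genotype": geno,
                                "dev_stage": int(
                                    developmental_stage(t, rate)),
                                "treatment": trt,
                                "soil": f"{site}_soil",
                                "sequencing_run": "run1",
                                "replicate": rep + 1,
                            })
    md = pd.DataFrame(rows)
    md.insert(0, "sample_id", [f"s{i:05d}" for i in range(len(md))])
    return validate_metadata(md)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_truth(n_otus: int = 300,
               archetype_fractions: dict | None = None,
               site_specific_early_fraction: float = 0.2,
               static_site_fraction: float = 0.1,
               midpoint_day: float = STAGE18_DEV_DAY,
               midpoint_sd: float = 25.0,
               sites: tuple = ("site_A", "site_B"),
               seed: int = 0) -> pd.DataFrame:
    """Draw per-OTU ground-truth parameters.

    Archetype mix defaults to 15% early, 25% late, 10% complex, 50%
    static; 20% of early OTUs are site-specific (they carry the early
    between-site differences), and 10% of static OTUs are bulk-soil-
    leaning site-specific taxa (persistent between-site soil differences).
    """
    if archetype_fractions is None:
        archetype_fractions = {"early": 0.15, "late": 0.25,
                               "complex": 0.10, "static": 0.50}
    rng = np.random.default_rng(seed)
    counts = {a: int(round(archetype_fractions.get(a, 0.0) * n_otus))
              for a in ARCHETYPES}
    counts["static"] = n_otus - sum(v for a, v in counts.items()
                                    if a != "static")
    archetypes = np.repeat(list(counts), list(counts.values()))

    rows = []
    for i, arch in enumerate(archetypes):
        baseline = rng.normal(0.0, 1.2)
        site_specific = "none"
        if arch in ("early", "late", "complex"):
            # successional root colonizers are moderately abundant taxa
            baseline = rng.normal(1.0, 1.0)
            slope = rng.normal(0.6, 0.4)
            amplitude = rng.uniform(2.0, 4.0)
            # keep the transition inside the observable season so every
            # dynamic OTU actually carries in-window signal
            mid = float(np.clip(rng.normal(midpoint_day, midpoint_sd),
                                30.0, 110.0))
            if arch == "complex":
                amplitude = rng.uniform(1.5, 3.0)
                mid = rng.uniform(40.0, 100.0)
            if arch == "early" and rng.random() < site_specific_early_fraction:
                site_specific = str(sites[int(rng.integers(len(sites)))])
                # site-specific taxa dominate the early-season root
                # community: abundant, and root-enriched so the
                # endosphere carries the strongest site signal
                baseline = rng.normal(2.0, 0.7)
                slope = rng.normal(1.0, 0.3)
        else:
            amplitude, mid = 0.0, midpoint_day
            if rng.random() < static_site_fraction:
                site_specific = str(sites[int(rng.integers(len(sites)))])
                slope = rng.normal(-1.0, 0.3)  # soil-resident
            else:
                slope = rng.normal(0.0, 0.4)
        rows.append({
            "otu_id": f"otu{i:05d}",
            "archetype": arch,
            "site_specific_to": site_specific,
            "affinity_slope": slope,
            "midpoint_day": mid,
            "amplitude": amplitude,
            "baseline": baseline,
            "drought_multiplier": 1.0,
        })
    truth = pd.DataFrame(rows).set_index("otu_id", drop=False)

    # Site-specific taxa come in niche-equivalent pairs, one per site:
    # each field hosts its own flora of comparable load, so shared taxa
    # carry no compositional site skew.
    for arch in ("early", "late", "complex", "static"):
        idx = truth.index[(truth["archetype"] == arch)
                          & (truth["site_specific_to"] != "none")]
        if len(idx) % 2:  # an unpaired taxon would unbalance the sites
            truth.loc[idx[-1], "site_specific_to"] = "none"
            idx = idx[:-1]
        for a, b in zip(idx[0::2], idx[1::2]):
            for col in ("affinity_slope", "midpoint_day", "amplitude",
                        "baseline"):
                truth.loc[b, col] = truth.loc[a, col]
            truth.loc[a, "site_specific_to"] = str(sites[0])
            truth.loc[b, "site_specific_to"] = str(sites[1])
    return truth


def make_taxonomy(truth: pd.DataFrame, seed: int = 0) -> TaxonomyTable:
    """Synthetic Greengenes-style lineages, phyla stratified by archetype."""
    rng = np.random.default_rng(seed)
    rows = {}
    for otu_id, rec in truth.iterrows():
        pool = _PHYLUM_POOL[rec["archetype"]]
        phylum, cls = pool[int(rng.integers(len(pool)))]
        rows[otu_id] = {
            "kingdom": "Bacteria" if phylum != "Euryarchaeota" else "Archaea",
            "phylum": phylum, "class": cls,
            "order": "unassigned", "family": "unassigned",
            "genus": "unassigned",
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index")
                         [list(RANKS)])


# ---------------------------------------------------------------------------
# latent dynamics
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def archetype_curve(archetype: str, dev_time, midpoint: float,
                    amplitude: float, scale: float = 10.0,
                    bump_width: float = 15.0) -> np.ndarray:
    """Succession curve contribution to log abundance at developmental time."""
    t = np.asarray(dev_time, dtype=float)
    if archetype == "early":
        return amplitude * (1.0 - _logistic((t - midpoint) / scale))
    if archetype == "late":
        return amplitude * _logistic((t - midpoint) / scale)
    if archetype == "complex":
        return amplitude * np.exp(-0.5 * ((t - midpoint) / bump_width) ** 2)
    if archetype == "static":
        return np.zeros_like(t)
    raise ValueError(f"unknown archetype {archetype!r}")


def simulate_dynamics(truth: pd.DataFrame, manifest: pd.DataFrame,
                      genotype_rates: dict | None = None,
                      curve_scale: float = 10.0,
                      bump_width: float = 15.0,
                      succession_position_weights=(0.0, 0.7, 0.9, 1.0),
                      ) -> pd.DataFrame:
    """Latent expected composition per sample (OTUs × samples, simplex cols).

    Succession is plant-driven, so the archetype curve is scaled by a
    per-position weight: zero in bulk soil (no plant to track) and
    strongest in the endosphere.
    """
    rates = (manifest["genotype"].map(genotype_rates)
             if genotype_rates else pd.Series(1.0, index=manifest.index))
    if rates.isna().any():
        raise ValueError("genotype missing from genotype_rates")
    dev_time = manifest["age_days"].to_numpy() * rates.to_numpy()
    positions = manifest["position"].to_numpy()
    weights = np.asarray(succession_position_weights)[positions]

    log_a = np.empty((len(truth), len(manifest)))
    for k, (_, rec) in enumerate(truth.iterrows()):
        log_a[k] = (rec["baseline"]
                    + rec["affinity_slope"] * positions
                    + weights * archetype_curve(
                        rec["archetype"], dev_time, rec["midpoint_day"],
                        rec["amplitude"], curve_scale, bump_width))
    comp = np.exp(log_a - log_a.max(axis=0, keepdims=True))

    # site-specific OTUs are absent outside their home site
    sites = manifest["site"].to_numpy()
    home = truth["site_specific_to"].to_numpy()
    comp = _zero_out_foreign_site(comp, home, sites)
    comp /= comp.sum(axis=0, keepdims=True)
    return pd.DataFrame(comp, index=truth.index,
                        columns=manifest["sample_id"].to_numpy())


def _zero_out_foreign_site(comp, home, sites):
    comp = comp.copy()
    for k in np.flatnonzero(home != "none"):
        comp[k, sites != home[k]] = 0.0
    return comp


def apply_drought_perturbation(latent: pd.DataFrame, manifest: pd.DataFrame,
                               truth: pd.DataFrame, severity: float,
                               rhizosphere_attenuation: float = 0.25,
                               ) -> pd.DataFrame:
    """Perturb drought-arm samples: early colonizers up, late down.

    Endosphere latent abundance of early archetypes is multiplied by
    (1 + severity) and late archetypes by 1/(1 + severity); the
    rhizosphere receives the same perturbation at ``severity ×
    rhizosphere_attenuation``. Bulk soil, rhizoplane and well-watered
    samples are untouched. Columns are renormalized to the simplex.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    known = {"well_watered", "drought", "none"}
    unknown = set(manifest["treatment"].unique()) - known
    if unknown:
        raise ValueError(f"unknown treatment labels: {sorted(unknown)}")
    out = latent.to_numpy().copy()
    early = (truth["archetype"] == "early").to_numpy()
    late = (truth["archetype"] == "late").to_numpy()
    comp = manifest["compartment"].to_numpy()
    drought = (manifest["treatment"] == "drought").to_numpy()
    for comp_name, sev in (("endosphere", severity),
                           ("rhizosphere", severity * rhizosphere_attenuation)):
        cols = drought & (comp == comp_name)
        if not cols.any() or sev == 0:
            continue
        out[np.ix_(early, cols)] *= 1.0 + sev
        out[np.ix_(late, cols)] /= 1.0 + sev
    out /= out.sum(axis=0, keepdims=True)
    return pd.DataFrame(out, index=latent.index, columns=latent.columns)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def sample_counts(latent: pd.DataFrame, mean_depth: float = 20000,
                  depth_sigma: float = 0.3,
                  dirichlet_concentration: float = 1000.0,
                  otu_noise_sigma: float = 0.5,
                  seed: int = 0) -> OtuTable:
    """Dirichlet-multinomial counts at log-normally distributed depths.

    ``otu_noise_sigma`` adds per-OTU, per-sample log-normal jitter to the
    latent composition before sampling — plant-to-plant heterogeneity
    that makes any single taxon a noisy predictor even when the
    community-level signal is strong.
    """
    if mean_depth < 100:
        raise ValueError("mean_depth must be >= 100")
    rng = np.random.default_rng(seed)
    p = latent.to_numpy()
    n_otus, n_samples = p.shape
    if otu_noise_sigma > 0:
        p = p * np.exp(rng.normal(0.0, otu_noise_sigma, size=p.shape))
        p = p / p.sum(axis=0, keepdims=True)
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        depth = max(100, int(round(
            np.exp(rng.normal(np.log(mean_depth), depth_sigma)))))
        support = p[:, j] > 0
        alpha = dirichlet_concentration * p[support, j]
        props = rng.dirichlet(alpha)
        counts[support, j] = rng.multinomial(depth, props)
    return OtuTable(pd.DataFrame(counts, index=latent.index,
                                 columns=latent.columns), unit=RAW_COUNTS)


# ---------------------------------------------------------------------------
# dataset assembly and fixtures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    table: OtuTable
    metadata: pd.DataFrame
    truth: pd.DataFrame
    taxonomy: TaxonomyTable
    params: dict


def simulate_dataset(design: SimulationDesign | None = None,
                     n_otus: int = 300,
                     archetype_fractions: dict | None = None,
                     site_specific_early_fraction: float = 0.2,
                     static_site_fraction: float = 0.1,
                     midpoint_day: float = STAGE18_DEV_DAY,
                     midpoint_sd: float = 25.0,
                     curve_scale: float = 10.0,
                     bump_width: float = 15.0,
                     succession_position_weights: tuple = (0.0, 0.7, 0.9, 1.0),
                     drought_severity: float = 0.8,
                     rhizosphere_attenuation: float = 0.25,
                     mean_depth: float = 20000,
                     depth_sigma: float = 0.3,
                     dirichlet_concentration: float = 1000.0,
                     otu_noise_sigma: float = 0.5,
                     ) -> SyntheticDataset:
    """Run the full generator: design → truth → dynamics → counts."""
    if design is None:
        design = SimulationDesign()
    params = {
        "design": {**asdict(design),
                   "sites": list(design.sites),
                   "compartments": list(design.compartments),
                   "timepoints_days": list(design.timepoints_days)},
        "n_otus": n_otus,
        "archetype_fractions": archetype_fractions,
        "site_specific_early_fraction": site_specific_early_fraction,
        "static_site_fraction": static_site_fraction,
        "midpoint_day": midpoint_day,
        "midpoint_sd": midpoint_sd,
        "curve_scale": curve_scale,
        "bump_width": bump_width,
        "succession_position_weights": list(succession_position_weights),
        "drought_severity": drought_severity,
        "rhizosphere_attenuation": rhizosphere_attenuation,
        "mean_depth": mean_depth,
        "depth_sigma": depth_sigma,
        "dirichlet_concentration": dirichlet_concentration,
        "otu_noise_sigma": otu_noise_sigma,
    }
    manifest = build_design(design)
    truth = make_truth(n_otus, archetype_fractions,
                       site_specific_early_fraction, static_site_fraction,
                       midpoint_day, midpoint_sd, tuple(design.sites),
                       seed=design.seed)
    latent = simulate_dynamics(truth, manifest, design.genotypes,
                               curve_scale, bump_width,
                               succession_position_weights)
    if design.drought_arms and drought_severity > 0:
        latent = apply_drought_perturbation(
            latent, manifest, truth, drought_severity,
            rhizosphere_attenuation)
        mult = np.where(truth["archetype"] == "early", 1.0 + drought_severity,
                        np.where(truth["archetype"] == "late",
                                 1.0 / (1.0 + drought_severity), 1.0))
        truth = truth.assign(drought_multiplier=mult)
    table = sample_counts(latent, mean_depth, depth_sigma,
                          dirichlet_concentration, otu_noise_sigma,
                          seed=design.seed + 1)
    taxonomy = make_taxonomy(truth, seed=design.seed + 2)
    return SyntheticDataset(table, manifest, truth, taxonomy, params)


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict:
    """Write otu_table.tsv, metadata.tsv, taxonomy.tsv, truth.tsv, params.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in (
        ("otu_table", "otu_table.tsv"), ("metadata", "metadata.tsv"),
        ("taxonomy", "taxonomy.tsv"), ("truth", "truth.tsv"),
        ("params", "params.json"))}
    write_otu_table(dataset.table, paths["otu_table"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["params"], "w") as fh:
        json.dump(dataset.params, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def replay_fixture(params_path) -> SyntheticDataset:
    """Regenerate a dataset from a recorded params.json."""
    with open(params_path) as fh:
        params = json.load(fh)
    d = params.pop("design")
    design = SimulationDesign(
        sites=tuple(d["sites"]), compartments=tuple(d["compartments"]),
        timepoints_days=tuple(d["timepoints_days"]),
        replicates_per_cell=d["replicates_per_cell"],
        genotypes=d["genotypes"], drought_arms=d["drought_arms"],
        seed=d["seed"])
    return simulate_dataset(design, **params)
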