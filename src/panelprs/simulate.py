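"""Synthetic cohorts with controlled LD, genotyping error and depth dropout.

The simulator produces a ground-truth dosage matrix plus two paired
observations of it:

* an "array + imputation" observation, where each call is independently
  miscalled with a per-variant probability, higher at imputed sites than at
  directly genotyped ones;
* a "targeted NGS" observation, where each call receives a read depth drawn
  from an overdispersed (negative-binomial) distribution, calls below a
  dropout depth are missing, and the genotype is the maximum-likelihood
  class given binomial read sampling of the two alleles with a symmetric
  per-read error.

Problem sites (low-complexity regions, systematically under-covered
targets) are built in, together with a proxy panel in controlled linkage
disequilibrium with them, so the proxy-substitution scoring path and the
whole validation battery can be exercised end to end.

The default geometry mirrors a 154-sample, 313-variant study with 105
array-genotyped / 208 imputed sites, 27 proxy substitutions (2 of them in
negative LD) and 2 unsequenceable sites scored as wild-type, with a global
mean target depth of 559x and 15 under-covered sites on the unoptimized
panel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genotypes import DepthTable, DosageMatrix, write_vcf
from .model import (
    ArrayStatus,
    Orientation,
    ProxyAction,
    ProxyMap,
    ProxyMapEntry,
    PrsModel,
    VariantDefinition,
    make_variant_id,
    save_model,
    save_proxy_map,
    save_variants,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study geometry and error-process parameters.

    Error rates are per-call (array) or per-read (NGS) probabilities;
    depths are mean reads per target.
    """

    n_samples: int = 154
    n_variants: int = 313
    n_genotyped: int = 105  # directly typed on the array; the rest are imputed
    n_indels: int = 46
    n_proxies: int = 27  # problem sites replaced by an LD surrogate
    n_negative: int = 2  # proxies in negative LD (dosage reversal)
    n_dead: int = 2  # sites with no usable surrogate -> assume wild-type
    n_low_depth: int = 15  # under-covered sites on the unoptimized panel
    proxy_r2_range: Tuple[float, float] = (0.47, 1.0)
    array_error_genotyped: float = 0.001
    array_error_imputed: float = 0.03
    mean_depth: float = 559.0
    low_depth_mean: float = 5.0
    depth_dispersion: float = 10.0
    dropout_depth: int = 8
    per_read_error: float = 0.001
    low_complexity_call_error: float = 0.30
    freq_range: Tuple[float, float] = (0.05, 0.95)
    weight_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_genotyped > self.n_variants:
            raise ValueError("n_genotyped cannot exceed n_variants")
        if self.n_proxies + self.n_dead > self.n_variants:
            raise ValueError("too many problem sites for the model size")
        if self.n_low_depth < self.n_dead:
            raise ValueError("dead sites are a subset of the low-depth sites")
        if self.n_negative > self.n_proxies:
            raise ValueError("n_negative cannot exceed n_proxies")
        for name in (
            "array_error_genotyped",
            "array_error_imputed",
            "per_read_error",
            "low_complexity_call_error",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        lo, hi = self.proxy_r2_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("proxy_r2_range must be within [0, 1]")


def feasible_r_range(p_a: float, p_b: float) -> Tuple[float, float]:
    """Range of the allelic correlation r attainable at given frequencies."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    denom = np.sqrt(p_a * q_a * p_b * q_b)
    d_min = max(-p_a * p_b, -q_a * q_b)
    d_max = min(p_a * q_b, q_a * p_b)
    return d_min / denom, d_max / denom


def haplotype_frequencies(
    p_a: float, p_b: float, r: float
) -> Tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) at correlation r."""
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    d = r * np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = (
        p_a * p_b + d,
        p_a * (1 - p_b) - d,
        (1 - p_a) * p_b - d,
        (1 - p_a) * (1 - p_b) + d,
    )
    if min(freqs) < -1e-12:
        lo, hi = feasible_r_range(p_a, p_b)
        raise ValueError(
            f"r = {r} infeasible at pA = {p_a}, pB = {p_b}; "
            f"feasible range is [{lo:.4f}, {hi:.4f}]"
        )
    return tuple(max(0.0, f) for f in freqs)


def simulate_two_locus_haplotypes(
    p_a: float,
    p_b: float,
    r_target: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw phased two-locus haplotype pairs for n diploid individuals.

    Returns an (n, 2, 2) array of 0/1 alleles indexed by individual,
    haplotype and locus, with 1 denoting the effect allele.  Haplotypes are
    drawn i.i.d. from the four-class distribution implied by the target
    allelic correlation.
    """
    freqs = haplotype_frequencies(p_a, p_b, r_target)
    draws = rng.choice(4, size=(n, 2), p=np.asarray(freqs) / sum(freqs))
    alleles_a = (draws <= 1).astype(np.int8)  # classes AB, Ab carry the A allele
    alleles_b = ((draws == 0) | (draws == 2)).astype(np.int8)  # AB, aB carry B
    return np.stack([alleles_a, alleles_b], axis=2)


def _random_snv_alleles(rng: np.random.Generator) -> Tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _random_indel_alleles(rng: np.random.Generator) -> Tuple[str, str]:
    anchor = str(_BASES[rng.integers(4)])
    inserted = "".join(_BASES[rng.integers(4, size=int(rng.integers(1, 4)))])
    if rng.random() < 0.5:
        return anchor, anchor + inserted  # insertion
    return anchor + inserted, anchor  # deletion


def generate_model(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[PrsModel, Dict[str, float], List[str]]:
    """Generate a synthetic PRS model.

    Returns the model, the per-variant effect-allele frequencies, and the
    ids of the "problem" sites (low-complexity / under-covered) that the
    proxy panel will target.  Problem sites are drawn from the imputed
    stratum, matching the observation that directly array-typed sites were
    unproblematic.
    """
    n = config.n_variants
    chroms = [str(c) for c in (np.arange(n) % 22 + 1)]
    offsets = rng.integers(1_000_000, 240_000_000, size=n)
    statuses = np.array(
        [ArrayStatus.GENOTYPED.value] * config.n_genotyped
        + [ArrayStatus.IMPUTED.value] * (n - config.n_genotyped)
    )
    rng.shuffle(statuses)
    imputed_idx = np.flatnonzero(statuses == ArrayStatus.IMPUTED.value)
    n_problem = config.n_proxies + config.n_dead
    problem_idx = set(rng.choice(imputed_idx, size=n_problem, replace=False).tolist())

    indel_idx = set(rng.choice(n, size=config.n_indels, replace=False).tolist())
    freqs: Dict[str, float] = {}
    variants: List[VariantDefinition] = []
    problem_ids: List[str] = []
    seen_positions = set()
    for i in range(n):
        if i in indel_idx:
            ref, alt = _random_indel_alleles(rng)
        else:
            ref, alt = _random_snv_alleles(rng)
        pos = int(offsets[i])
        while (chroms[i], pos) in seen_positions:
            pos += 1
        seen_positions.add((chroms[i], pos))
        effect = alt if rng.random() < 0.5 else ref
        vid = make_variant_id(chroms[i], pos, ref, alt)
        variant = VariantDefinition(
            variant_id=vid,
            chromosome=chroms[i],
            position=pos,
            ref_allele=ref,
            alt_allele=alt,
            effect_allele=effect,
            weight=float(rng.normal(0.0, config.weight_sd)),
            array_status=ArrayStatus(statuses[i]),
            low_complexity=i in problem_idx,
        )
        variants.append(variant)
        freqs[vid] = float(rng.uniform(*config.freq_range))
        if i in problem_idx:
            problem_ids.append(vid)
    return PrsModel(name="synthetic_prs", variants=tuple(variants)), freqs, problem_ids


def design_proxy_panel(
    model: PrsModel,
    problem_ids: Sequence[str],
    freqs: Dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[ProxyMap, List[VariantDefinition], Dict[str, float]]:
    """Build the proxy map and surrogate variant definitions.

    The first ``n_dead`` problem sites get an assume-wildtype entry; the
    rest get a surrogate within 50 kb whose target r2 is drawn from
    ``proxy_r2_range``, with the first ``n_negative`` substitutions in
    negative LD.  Surrogate effect-allele frequencies are chosen to make
    any requested r2 feasible (equal to the target's for positive LD, its
    complement for negative LD).

    Returns the map, the surrogate variant definitions (weight 0; they
    carry no score of their own) and the per-pair target r values keyed by
    original id (signed: negative for reversed orientation).
    """
    proxy_map: ProxyMap = {}
    proxy_variants: List[VariantDefinition] = []
    r_targets: Dict[str, float] = {}
    dead = list(problem_ids[: config.n_dead])
    substituted = list(problem_ids[config.n_dead :])
    for vid in dead:
        proxy_map[vid] = ProxyMapEntry(
            original_id=vid,
            proxy_id="",
            r2=0.0,
            d_prime=0.0,
            orientation=Orientation.POSITIVE,
            action=ProxyAction.ASSUME_WILDTYPE,
        )
    for k, vid in enumerate(substituted):
        original = model[vid]
        negative = k < config.n_negative
        r2 = float(rng.uniform(*config.proxy_r2_range))
        r = np.sqrt(r2) * (-1.0 if negative else 1.0)
        ref, alt = _random_snv_alleles(rng)
        pos = original.position + int(rng.integers(500, 50_000))
        proxy_id = make_variant_id(original.chromosome, pos, ref, alt)
        proxy_variants.append(
            VariantDefinition(
                variant_id=proxy_id,
                chromosome=original.chromosome,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                effect_allele=alt if rng.random() < 0.5 else ref,
                weight=0.0,
                array_status=ArrayStatus.GENOTYPED,
                low_complexity=False,
            )
        )
        # with pB = pA (positive) or 1 - pA (negative), |r| up to 1 is feasible
        # and D' equals |r| analytically
        proxy_map[vid] = ProxyMapEntry(
            original_id=vid,
            proxy_id=proxy_id,
            r2=float(r2),
            d_prime=float(abs(r)),
            orientation=Orientation.NEGATIVE if negative else Orientation.POSITIVE,
            action=ProxyAction.SUBSTITUTE,
        )
        r_targets[vid] = float(r)
    return proxy_map, proxy_variants, r_targets


@dataclass
class SimulatedCohort:
    """Ground truth plus the design artifacts needed to observe and score it."""

    config: SimulationConfig
    model: PrsModel
    proxy_map: ProxyMap
    proxy_variants: List[VariantDefinition]
    truth: DosageMatrix  # samples x (model variants + surrogate variants)
    freqs: Dict[str, float]  # effect-allele frequency per variant (incl. proxies)
    problem_ids: List[str]
    dead_ids: List[str]
    low_depth_ids: List[str]

    @property
    def panel_variants(self) -> List[VariantDefinition]:
        return list(self.model.variants) + list(self.proxy_variants)

    def truth_model_only(self) -> DosageMatrix:
        return self.truth.select(self.model.variant_ids)


def simulate_truth_cohort(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedCohort:
    """Simulate the ground-truth cohort.

    Unlinked variants draw dosages binomial(2, freq); each proxied site and
    its surrogate are drawn jointly from the two-locus haplotype
    distribution at the designed r.  Output is reproducible for a fixed
    config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model, freqs, problem_ids = generate_model(config, rng)
    proxy_map, proxy_variants, r_targets = design_proxy_panel(
        model, problem_ids, freqs, config, rng
    )
    dead_ids = [
        e.original_id
        for e in proxy_map.values()
        if e.action is ProxyAction.ASSUME_WILDTYPE
    ]
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    linked = {e.proxy_id: e.original_id for e in proxy_map.values() if e.proxy_id}
    columns = [v.variant_id for v in model.variants] + [
        v.variant_id for v in proxy_variants
    ]
    data = pd.DataFrame(index=sample_ids, columns=columns, dtype=float)
    for v in model.variants:
        entry = proxy_map.get(v.variant_id)
        if entry is not None and entry.action is ProxyAction.SUBSTITUTE:
            continue  # drawn jointly with its surrogate below
        data[v.variant_id] = rng.binomial(2, freqs[v.variant_id], size=config.n_samples)
    for proxy in proxy_variants:
        original_id = linked[proxy.variant_id]
        p_a = freqs[original_id]
        r = r_targets[original_id]
        p_b = p_a if r >= 0 else 1.0 - p_a
        freqs[proxy.variant_id] = p_b
        haps = simulate_two_locus_haplotypes(p_a, p_b, r, config.n_samples, rng)
        data[original_id] = haps[:, :, 0].sum(axis=1).astype(float)
        data[proxy.variant_id] = haps[:, :, 1].sum(axis=1).astype(float)
    data = data.astype(float)
    # under-covered sites on the unoptimized panel: all dead sites plus a
    # draw from the remaining problem sites
    pool = [vid for vid in problem_ids if vid not in dead_ids]
    extra = rng.choice(
        pool, size=config.n_low_depth - len(dead_ids), replace=False
    ).tolist()
    low_depth_ids = dead_ids + extra
    return SimulatedCohort(
        config=config,
        model=model,
        proxy_map=proxy_map,
        proxy_variants=proxy_variants,
        truth=DosageMatrix(data),
        freqs=freqs,
        problem_ids=problem_ids,
        dead_ids=dead_ids,
        low_depth_ids=low_depth_ids,
    )


def simulate_array_observation(
    truth: DosageMatrix,
    model: PrsModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> DosageMatrix:
    """Observe the truth through array genotyping + imputation.

    Each call is independently replaced by one of the other two genotype
    classes (uniformly) with the per-variant miscall probability of its
    array status.  Surrogate panel variants are not on the array and are
    dropped.
    """
    n = len(truth.sample_ids)
    data = pd.DataFrame(index=truth.data.index, columns=model.variant_ids, dtype=float)
    for v in model.variants:
        rate = (
            config.array_error_genotyped
            if v.array_status is ArrayStatus.GENOTYPED
            else config.array_error_imputed
        )
        calls = truth.data[v.variant_id].to_numpy(dtype=float).copy()
        flip = rng.random(n) < rate
        shift = rng.integers(1, 3, size=n)  # 1 or 2 -> uniform over the other classes
        calls[flip] = (calls[flip] + shift[flip]) % 3
        data[v.variant_id] = calls
    return DosageMatrix(data)


def ngs_site_profile(cohort: SimulatedCohort, optimized: bool = True) -> pd.DataFrame:
    """Per-panel-variant depth and error profile for the NGS run.

    Dead sites have mean depth 0 (unsequenceable); the other under-covered
    sites get the low mean.  Low-complexity sites additionally carry a
    per-call miscall probability modelling systematic misalignment in
    homopolymer/repeat context, which unlike random read error does not
    average out with depth.  Surrogates and clean sites sequence at the
    configured mean with the baseline read error only.  With
    ``optimized=False`` the surrogate variants are absent (the unoptimized
    panel did not include them).
    """
    config = cohort.config
    rows = []
    variants = cohort.panel_variants if optimized else list(cohort.model.variants)
    low_depth = set(cohort.low_depth_ids)
    dead = set(cohort.dead_ids)
    for v in variants:
        vid = v.variant_id
        if vid in dead:
            mean, call_err = 0.0, 0.0
        elif vid in low_depth:
            mean, call_err = config.low_depth_mean, config.low_complexity_call_error
        elif v.low_complexity:
            mean, call_err = config.mean_depth, config.low_complexity_call_error
        else:
            mean, call_err = config.mean_depth, 0.0
        rows.append(
            {
                "variant_id": vid,
                "mean_depth": mean,
                "read_error": config.per_read_error,
                "call_error": call_err,
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def simulate_ngs_observation(
    truth: DosageMatrix,
    profile: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[DosageMatrix, DepthTable]:
    """Observe the truth through targeted sequencing.

    Per cell: depth ~ negative binomial with the site's mean and the
    configured dispersion; depth below the dropout threshold -> missing
    call; otherwise effect-allele reads ~ binomial(depth, q) with
    q in {e, 1/2, 1-e} by true dosage, and the called dosage is the
    maximum-likelihood genotype class.  Sites with a nonzero per-call error
    (low-complexity context) then have the call replaced by one of the
    other two classes, uniformly, with that probability.
    """
    n = len(truth.sample_ids)
    variant_ids = [vid for vid in profile.index if vid in truth.data.columns]
    calls = pd.DataFrame(index=truth.data.index, columns=variant_ids, dtype=float)
    depths = pd.DataFrame(0, index=truth.data.index, columns=variant_ids, dtype=int)
    size = config.depth_dispersion
    for vid in variant_ids:
        mean = float(profile.at[vid, "mean_depth"])
        err = float(profile.at[vid, "read_error"])
        call_err = float(profile.at[vid, "call_error"])
        if mean <= 0:
            depth = np.zeros(n, dtype=int)
        else:
            depth = rng.negative_binomial(size, size / (size + mean), size=n)
        depths[vid] = depth
        true_dosage = truth.data[vid].to_numpy(dtype=float)
        q_by_dosage = np.array([err, 0.5, 1.0 - err])
        q = q_by_dosage[true_dosage.astype(int)]
        k = rng.binomial(depth, q)
        called = _ml_genotype(k, depth, err).astype(float)
        if call_err > 0:
            flip = rng.random(n) < call_err
            shift = rng.integers(1, 3, size=n)
            called[flip] = (called[flip] + shift[flip]) % 3
        called[depth < config.dropout_depth] = np.nan
        calls[vid] = called
    return DosageMatrix(calls), DepthTable(depths)


def _ml_genotype(k: np.ndarray, depth: np.ndarray, read_error: float) -> np.ndarray:
    """Maximum-likelihood genotype from k effect-allele reads out of depth."""
    e = min(max(read_error, 1e-12), 0.5)
    d = np.maximum(depth, 1)  # avoid log(0) weights; depth-0 cells drop out anyway
    logliks = np.stack(
        [
            k * np.log(q) + (d - k) * np.log(1.0 - q)
            for q in (e, 0.5, 1.0 - e)
        ],
        axis=0,
    )
    return np.argmax(logliks, axis=0)


@dataclass
class StudyBundle:
    """A complete simulated method-comparison study."""

    cohort: SimulatedCohort
    array_obs: DosageMatrix
    ngs_obs: DosageMatrix  # optimized panel: model + surrogate variants
    ngs_depths: DepthTable
    ngs_obs_original: DosageMatrix  # unoptimized panel: model variants only
    ngs_depths_original: DepthTable


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Run the full pipeline: truth, array observation, both NGS panels."""
    rng = np.random.default_rng(config.seed)
    cohort = simulate_truth_cohort(config, rng)
    array_obs = simulate_array_observation(cohort.truth, cohort.model, config, rng)
    ngs_obs, ngs_depths = simulate_ngs_observation(
        cohort.truth, ngs_site_profile(cohort, optimized=True), config, rng
    )
    ngs_obs_orig, ngs_depths_orig = simulate_ngs_observation(
        cohort.truth, ngs_site_profile(cohort, optimized=False), config, rng
    )
    return StudyBundle(
        cohort=cohort,
        array_obs=array_obs,
        ngs_obs=ngs_obs,
        ngs_depths=ngs_depths,
        ngs_obs_original=ngs_obs_orig,
        ngs_depths_original=ngs_depths_orig,
    )


def synthetic_lifetime_risk(prs: float) -> float:
    """Synthetic monotone PRS -> lifetime-risk-% mapping for demonstrations.

    A stand-in curve anchored near an 11.5 % population lifetime risk at
    PRS 0; it is NOT a risk model, only a monotone transform so that the
    categorization workflow can be exercised on simulated scores.
    """
    return 11.5 * float(np.exp(0.35 * prs))


def write_fixture_set(bundle: StudyBundle, outdir: Union[str, Path]) -> Dict[str, str]:
    """Write a simulated study to disk in the formats the toolkit consumes.

    Emits the model and proxy-map TSVs, the surrogate-variant table,
    truth/array/NGS VCFs, per-site depth TSVs and a manifest recording the
    configuration and seed.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = bundle.cohort
    paths = {
        "model": outdir / "model.tsv",
        "proxy_map": outdir / "proxy_map.tsv",
        "panel_extra": outdir / "panel_extra.tsv",
        "truth_vcf": outdir / "truth.vcf",
        "array_vcf": outdir / "array.vcf",
        "ngs_vcf": outdir / "ngs_optimized.vcf",
        "ngs_original_vcf": outdir / "ngs_original.vcf",
        "depths": outdir / "ngs_depths.tsv",
        "manifest": outdir / "manifest.json",
    }
    save_model(cohort.model, paths["model"])
    save_proxy_map(cohort.proxy_map, paths["proxy_map"])
    save_variants(cohort.proxy_variants, paths["panel_extra"])
    write_vcf(paths["truth_vcf"], cohort.panel_variants, cohort.truth)
    write_vcf(paths["array_vcf"], cohort.model, bundle.array_obs)
    write_vcf(paths["ngs_vcf"], cohort.panel_variants, bundle.ngs_obs)
    write_vcf(paths["ngs_original_vcf"], cohort.model, bundle.ngs_obs_original)
    bundle.ngs_depths.to_tsv(paths["depths"], cohort.panel_variants)
    manifest = {"config": asdict(bundle.cohort.config)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
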