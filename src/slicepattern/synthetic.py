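"""Synthetic sliced-embryo expression cohorts with known ground truth.

Generates per-embryo gene x slice FPKM matrices from parametric AP patterns
(exponential gradients, Gaussian domains, raised-cosine stripes), applies
genotype-dependent effect operators (loss, uniformisation, shift, ectopic
gain, level scaling), adds multiplicative lognormal noise and random QC
failures, and emits a truth table for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import emd_to_uniform

__all__ = [
    "PATTERN_FAMILIES",
    "GENOTYPES",
    "EFFECTS",
    "EXPRESSED_FPKM",
    "PatternSpec",
    "GenotypeEffect",
    "CohortConfig",
    "EmbryoSample",
    "evaluate_pattern",
    "apply_effect",
    "slice_embryo",
    "random_pattern_spec",
    "generate_cohort",
    "generate_binding_tracks",
    "true_pattern_class",
]

PATTERN_FAMILIES = (
    "uniform",
    "anterior_gradient",
    "posterior_gradient",
    "anterior_domain",
    "posterior_domain",
    "central_domain",
    "stripes",
)
GENOTYPES = ("wt", "bcd_minus", "bcd_2.4x", "hb_minus", "zld_minus")
EFFECTS = ("none", "loss_to_low", "uniformize", "shift", "ectopic_gain", "level_scale")

#: expressed-gene floor: at least this FPKM in at least one slice
EXPRESSED_FPKM = 15.0

_DOMAIN_CENTERS = {"anterior_domain": 0.15, "posterior_domain": 0.85,
                   "central_domain": 0.5}


@dataclass(frozen=True)
class PatternSpec:
    """Parametric noise-free AP expression pattern for one gene.

    ``params`` keys by family:

    * uniform — ``amplitude``
    * anterior_gradient / posterior_gradient — ``amplitude``, ``decay_length``
      (fraction of embryo length), optional ``origin`` (gradient start, default
      0 for anterior, 1 for posterior)
    * anterior/posterior/central_domain — ``amplitude``, ``center``, ``width``
      (Gaussian s.d., fractions of embryo length)
    * stripes — ``amplitude``, ``n_stripes`` (>= 1), optional ``phase``

    Any family may carry ``extra_domains``: a list of ``{center, width,
    amplitude}`` Gaussian terms added on top (used for ectopic gain).
    """

    gene_id: str
    family: str
    params: dict = field(default_factory=dict)
    baseline: float = 0.0

    def __post_init__(self):
        if self.family not in PATTERN_FAMILIES:
            raise ValueError(f"unknown pattern family: {self.family!r}")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.params.get("amplitude", 0.0) < 0:
            raise ValueError("amplitude must be >= 0")
        center = self.params.get("center")
        if center is not None and not 0.0 <= center <= 1.0:
            raise ValueError("center must be in [0, 1]")
        for key in ("width", "decay_length"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"{key} must be > 0")
        if self.family == "stripes" and self.params.get("n_stripes", 1) < 1:
            raise ValueError("n_stripes must be >= 1")


@dataclass(frozen=True)
class GenotypeEffect:
    """How one genotype perturbs one gene's pattern."""

    gene_id: str
    genotype: str
    effect: str = "none"
    effect_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype: {self.genotype!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect: {self.effect!r}")
        if self.genotype == "wt" and self.effect != "none":
            raise ValueError("wild type must carry effect 'none'")
        shift = self.effect_params.get("distance")
        if shift is not None and not -1.0 <= shift <= 1.0:
            raise ValueError("shift distance must be in [-1, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort (genotypes x timepoints x replicates)."""

    n_genes: int = 500
    genotypes: tuple = GENOTYPES
    timepoints: tuple = (13, 14)
    replicates_per_timepoint: int = 2
    slice_count_range: tuple = (25, 30)
    noise_sigma: float = 0.15
    qc_fail_rate: float = 0.02
    effect_probability: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if len(self.genotypes) == 0:
            raise ValueError("genotype list must be non-empty")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")
        lo, hi = self.slice_count_range
        if lo < 5 or hi < lo:
            raise ValueError("slice_count_range must satisfy 5 <= min <= max")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.qc_fail_rate <= 1.0:
            raise ValueError("qc_fail_rate must be in [0, 1]")


@dataclass(frozen=True)
class EmbryoSample:
    """One sliced embryo: metadata plus a genes x slices FPKM matrix.

    ``qc_mask`` is per slice, True = passed QC.
    """

    embryo_id: str
    genotype: str
    stage: int
    gene_ids: tuple
    values: np.ndarray
    qc_mask: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.qc_mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "qc_mask", mask)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if values.shape != (len(self.gene_ids), mask.size):
            raise ValueError("values shape must be (n_genes, n_slices)")

    @property
    def n_slices(self) -> int:
        return self.qc_mask.size


def evaluate_pattern(spec: PatternSpec, x):
    """Noise-free mean expression (FPKM) at fractional AP position(s) x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must be in [0, 1]")
    p = spec.params
    amp = p.get("amplitude", 0.0)
    if spec.family == "uniform":
        val = np.full_like(x, amp, dtype=float)
    elif spec.family == "anterior_gradient":
        origin = p.get("origin", 0.0)
        val = amp * np.exp(-np.maximum(x - origin, 0.0) / p["decay_length"])
    elif spec.family == "posterior_gradient":
        origin = p.get("origin", 1.0)
        val = amp * np.exp(-np.maximum(origin - x, 0.0) / p["decay_length"])
    elif spec.family in _DOMAIN_CENTERS:
        center = p.get("center", _DOMAIN_CENTERS[spec.family])
        val = amp * np.exp(-((x - center) / p["width"]) ** 2 / 2.0)
    elif spec.family == "stripes":
        n = p.get("n_stripes", 1)
        phase = p.get("phase", 0.0)
        val = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * n * x + phase))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown pattern family: {spec.family!r}")
    for dom in p.get("extra_domains", ()):
        val = val + dom["amplitude"] * np.exp(
            -((x - dom["center"]) / dom["width"]) ** 2 / 2.0)
    out = val + spec.baseline
    return float(out) if out.ndim == 0 else out


def _pattern_max(spec: PatternSpec, n_grid: int = 2001) -> float:
    return float(np.max(evaluate_pattern(spec, np.linspace(0.0, 1.0, n_grid))))


def _pattern_mean(spec: PatternSpec, n_grid: int = 2001) -> float:
    return float(np.mean(evaluate_pattern(spec, np.linspace(0.0, 1.0, n_grid))))


def apply_effect(spec: PatternSpec, effect: GenotypeEffect) -> PatternSpec:
    """Return the pattern a genotype produces for this gene.

    * ``loss_to_low`` rescales so the peak falls below the 15 FPKM expressed
      floor (to ``target_max``, default 5 FPKM).
    * ``uniformize`` flattens to a uniform pattern with the same embryo-wide
      mean expression.
    * ``shift`` translates the domain centre / gradient origin by
      ``distance`` (fraction of embryo length), clipped to [0, 1].
    * ``ectopic_gain`` adds a Gaussian domain (``center``, ``width``,
      ``amplitude``; defaults 0.15 / 0.08 / pattern peak).
    * ``level_scale`` multiplies amplitude and baseline by ``factor``.
    """
    kind = effect.effect
    ep = effect.effect_params
    if kind == "none":
        return spec
    if kind == "loss_to_low":
        target = ep.get("target_max", 5.0)
        if not 0 <= target < EXPRESSED_FPKM:
            raise ValueError(f"target_max must be in [0, {EXPRESSED_FPKM})")
        peak = _pattern_max(spec)
        scale = target / peak if peak > 0 else 0.0
        return _scale_spec(spec, scale)
    if kind == "uniformize":
        return PatternSpec(spec.gene_id, "uniform",
                           {"amplitude": _pattern_mean(spec)}, baseline=0.0)
    if kind == "shift":
        dist = ep["distance"]
        params = dict(spec.params)
        if spec.family in _DOMAIN_CENTERS:
            center = params.get("center", _DOMAIN_CENTERS[spec.family])
            params["center"] = float(np.clip(center + dist, 0.0, 1.0))
        elif spec.family == "anterior_gradient":
            params["origin"] = float(np.clip(params.get("origin", 0.0) + dist, 0.0, 1.0))
        elif spec.family == "posterior_gradient":
            params["origin"] = float(np.clip(params.get("origin", 1.0) + dist, 0.0, 1.0))
        elif spec.family == "stripes":
            n = params.get("n_stripes", 1)
            params["phase"] = params.get("phase", 0.0) - 2.0 * np.pi * n * dist
        if "extra_domains" in params:
            params["extra_domains"] = [
                {**d, "center": float(np.clip(d["center"] + dist, 0.0, 1.0))}
                for d in params["extra_domains"]]
        return replace(spec, params=params)
    if kind == "ectopic_gain":
        params = dict(spec.params)
        dom = {"center": ep.get("center", 0.15),
               "width": ep.get("width", 0.08),
               "amplitude": ep.get("amplitude", max(_pattern_max(spec), 20.0))}
        params["extra_domains"] = list(params.get("extra_domains", ())) + [dom]
        return replace(spec, params=params)
    if kind == "level_scale":
        factor = ep.get("factor", 1.0)
        if factor <= 0:
            raise ValueError("level_scale factor must be > 0")
        return _scale_spec(spec, factor)
    raise ValueError(f"unknown effect: {kind!r}")  # pragma: no cover


def _scale_spec(spec: PatternSpec, factor: float) -> PatternSpec:
    params = dict(spec.params)
    params["amplitude"] = params.get("amplitude", 0.0) * factor
    if "extra_domains" in params:
        params["extra_domains"] = [
            {**d, "amplitude": d["amplitude"] * factor}
            for d in params["extra_domains"]]
    return replace(spec, params=params, baseline=spec.baseline * factor)


# 32 midpoint sub-samples per slice approximate the physical integral
_SUBSAMPLES = 32


def slice_profile_values(spec: PatternSpec, n_slices: int) -> np.ndarray:
    """Noise-free per-slice values: interval means of the continuous pattern."""
    sub = (np.arange(n_slices * _SUBSAMPLES) + 0.5) / (n_slices * _SUBSAMPLES)
    return evaluate_pattern(spec, sub).reshape(n_slices, _SUBSAMPLES).mean(axis=1)


def slice_embryo(specs, n_slices: int, noise_sigma: float, qc_fail_rate: float,
                 seed, *, embryo_id: str = "embryo", genotype: str = "wt",
                 stage: int = 14) -> EmbryoSample:
    """Slice an embryo into N equal-width AP slices and measure each gene.

    Slice i covers [i/N, (i+1)/N); the stored value is the interval mean of
    the pattern times a lognormal(0, sigma) noise factor drawn per gene per
    slice.  Each slice fails QC independently with probability
    ``qc_fail_rate``.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_slices < 5:
        raise ValueError("n_slices must be >= 5")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.stack([slice_profile_values(s, n_slices) for s in specs])
    if noise_sigma > 0:
        values = values * rng.lognormal(0.0, noise_sigma, size=values.shape)
    qc_mask = rng.random(n_slices) >= qc_fail_rate
    return EmbryoSample(embryo_id, genotype, stage,
                        tuple(s.gene_id for s in specs), values, qc_mask)


def random_pattern_spec(gene_id: str, rng: np.random.Generator,
                        family: str | None = None) -> PatternSpec:
    """Draw a plausible wild-type pattern for one gene."""
    if family is None:
        family = rng.choice(PATTERN_FAMILIES,
                            p=[0.40, 0.12, 0.12, 0.12, 0.08, 0.08, 0.08])
    amplitude = float(rng.lognormal(np.log(80.0), 0.8))
    baseline = float(rng.uniform(0.0, 3.0))
    params: dict = {"amplitude": amplitude}
    if family.endswith("_gradient"):
        params["decay_length"] = float(rng.uniform(0.1, 0.3))
    elif family.endswith("_domain"):
        base = _DOMAIN_CENTERS[family]
        params["center"] = float(np.clip(base + rng.normal(0.0, 0.05), 0.0, 1.0))
        params["width"] = float(rng.uniform(0.04, 0.10))
    elif family == "stripes":
        params["n_stripes"] = int(rng.integers(2, 8))
        params["phase"] = float(rng.uniform(0.0, 2.0 * np.pi))
    return PatternSpec(gene_id, family, params, baseline)


_MUTANT_EFFECT_CHOICES = ("loss_to_low", "uniformize", "shift", "ectopic_gain",
                          "level_scale")
_MUTANT_EFFECT_WEIGHTS = (0.3, 0.3, 0.2, 0.1, 0.1)


def _random_effect(gene_id: str, genotype: str,
                   rng: np.random.Generator) -> GenotypeEffect:
    kind = rng.choice(_MUTANT_EFFECT_CHOICES, p=_MUTANT_EFFECT_WEIGHTS)
    params: dict = {}
    if kind == "shift":
        params["distance"] = float(rng.uniform(0.05, 0.25) * rng.choice([-1, 1]))
    elif kind == "level_scale":
        params["factor"] = float(rng.choice([rng.uniform(1.5, 3.0),
                                             rng.uniform(0.2, 0.67)]))
    elif kind == "ectopic_gain":
        params["center"] = float(rng.uniform(0.05, 0.95))
        params["width"] = float(rng.uniform(0.05, 0.12))
    return GenotypeEffect(gene_id, genotype, kind, params)


def true_pattern_class(spec: PatternSpec, n_slices: int = 27,
                       expressed_fpkm: float = EXPRESSED_FPKM,
                       uniform_emd: float = 0.04,
                       patterned_emd: float = 0.08) -> str:
    """Ground-truth pattern class of a noise-free spec at a reference N."""
    values = slice_profile_values(spec, n_slices)
    if values.max() < expressed_fpkm:
        return "low_expression"
    d = emd_to_uniform(values)
    if d < uniform_emd:
        return "uniform"
    if d > patterned_emd:
        return "patterned"
    return "ambiguous"


def generate_cohort(config: CohortConfig, specs=None, effects=None):
    """Generate the full cohort and its truth table.

    Returns ``(embryos, truth)`` where ``embryos`` holds one
    :class:`EmbryoSample` per genotype x timepoint x replicate (slice counts
    drawn per embryo from ``slice_count_range``) and ``truth`` is a DataFrame
    with one row per (gene, genotype): family, effect applied, params as a
    JSON string, and the true pattern class.

    ``specs`` (wild-type patterns) and ``effects`` (mapping
    ``(gene_id, genotype) -> GenotypeEffect``) may be supplied explicitly;
    otherwise they are drawn from the config's seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    if specs is None:
        specs = [random_pattern_spec(g, rng) for g in gene_ids]
    else:
        gene_ids = [s.gene_id for s in specs]
    if effects is None:
        effects = {}
        for genotype in config.genotypes:
            if genotype == "wt":
                continue
            for g in gene_ids:
                if rng.random() < config.effect_probability:
                    effects[(g, genotype)] = _random_effect(g, genotype, rng)

    genotype_specs = {}
    for genotype in config.genotypes:
        genotype_specs[genotype] = [
            apply_effect(s, effects[(s.gene_id, genotype)])
            if (s.gene_id, genotype) in effects else s
            for s in specs]

    lo, hi = config.slice_count_range
    embryos = []
    for genotype in config.genotypes:
        for tp in config.timepoints:
            for rep in range(1, config.replicates_per_timepoint + 1):
                n_slices = int(rng.integers(lo, hi + 1))
                embryo_id = f"{genotype.replace('.', 'p')}-T{tp}-R{rep}"
                embryos.append(slice_embryo(
                    genotype_specs[genotype], n_slices, config.noise_sigma,
                    config.qc_fail_rate, rng, embryo_id=embryo_id,
                    genotype=genotype, stage=tp))

    rows = []
    for genotype in config.genotypes:
        for spec, eff_spec in zip(specs, genotype_specs[genotype]):
            eff = effects.get((spec.gene_id, genotype))
            rows.append({
                "gene_id": spec.gene_id,
                "genotype": genotype,
                "family": eff_spec.family,
                "effect": eff.effect if eff is not None else "none",
                "params": json.dumps({"params": eff_spec.params,
                                      "baseline": eff_spec.baseline},
                                     sort_keys=True),
                "true_class": true_pattern_class(eff_spec),
            })
    truth = pd.DataFrame(rows)
    return embryos, truth


_DEFAULT_TFS = ("bcd", "cad", "D", "gt", "hb", "hkb", "kni", "kr", "tll", "zld")


def generate_binding_tracks(gene_ids, affected_genes, seed, *,
                            tfs=_DEFAULT_TFS, enriched_tf: str = "bcd",
                            affected_rate: float = 0.6,
                            background_rate: float = 0.15,
                            gene_spacing: int = 50_000,
                            n_enhancers: int = 40):
    """Synthetic TSS/ChIP-peak/enhancer annotations coupled to the truth table.

    Genes are laid out every ``gene_spacing`` bp along one chromosome.  The
    ``enriched_tf`` binds genes in ``affected_genes`` at ``affected_rate`` and
    the rest at ``background_rate``; every other TF binds independently at
    ``background_rate``.  A bound gene gets one peak within 10 kb of its TSS.
    Enhancer intervals are placed near a sample of enriched-TF peaks.

    Returns ``(tss, peaks, enhancers)`` as plain DataFrames in the
    :mod:`slicepattern.io_formats` dialects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    affected = set(affected_genes)
    tss = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": "chr2L",
        "position": [gene_spacing * (i + 1) for i in range(len(gene_ids))],
        "strand": [("+", "-")[int(rng.random() < 0.5)] for _ in gene_ids],
    })
    peak_rows = []
    for i, g in enumerate(gene_ids):
        pos0 = gene_spacing * (i + 1) - 1
        for tf in tfs:
            rate = (affected_rate if g in affected else background_rate) \
                if tf == enriched_tf else background_rate
            if rng.random() < rate:
                offset = int(rng.integers(-9_500, 9_500))
                start = max(pos0 + offset - 150, 0)
                peak_rows.append(("chr2L", start, start + 300, tf,
                                  float(np.round(rng.uniform(1, 100), 2))))
    peaks = pd.DataFrame(peak_rows,
                         columns=["chrom", "start", "end", "name", "score"])
    source = peaks[peaks["name"] == enriched_tf]
    enh_rows = []
    for k in range(n_enhancers):
        if len(source) and rng.random() < 0.8:
            row = source.iloc[int(rng.integers(len(source)))]
            center = int((row.start + row.end) // 2 + rng.integers(-2_000, 2_000))
        else:  # orphan enhancer far from any TSS
            center = int(rng.integers(1, gene_spacing * (len(gene_ids) + 1)))
        enh_rows.append(("chr2L", max(center - 500, 0), center + 500,
                         f"enh{k:03d}", 0.0))
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "name", "score"])
    return tss, peaks, enhancers
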