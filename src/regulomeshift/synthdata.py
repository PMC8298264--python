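"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: a 2-condition
(WT vs knockdown) x 3-replicate expression experiment with planted
differentially expressed genes and planted "functional complement" genes
(jointly up-regulated and broadly annotated, the two ingredients of a
network-centrality gain); a gene->BP annotation bipartite structure whose BP
set has a designated interacting-protein coverage gap; peptide-array grids
with empty control spots; and single-site ITC thermograms.

Replicate noise is multiplicative log-normal (the pipeline consumes
normalized abundances, not raw counts), parameterized by the coefficient of
variation and mean-corrected so the expected value equals the planted mean.
Every generator is deterministic under (config, seed); distinct substreams
are derived per generator so the outputs stay consistent when generators
are called independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    AnnotationTable,
    ExpressionMatrix,
    IPAnnotationTable,
    KO,
    WT,
)
from .arraystats import PeptideArray
from .itcfit import ITCProtocol, simulate_isotherm

_STREAM_EXPRESSION = 1
_STREAM_ANNOTATION = 2
_STREAM_ARRAY = 3
_STREAM_ITC = 4


@dataclass(frozen=True)
class ComplementSpec:
    """A planted functional complement.

    Mirrors the observed profile of candidate complements: essentially
    silent in wildtype (``wt_level``, normalized expression units at the
    detection floor), switched on after knockdown (``fold_gain``; the most
    up-regulated candidate carries a log2 fold change of about +6.4, i.e.
    an 84-fold induction), and broadly annotated (``n_bps`` process
    memberships).
    """

    gene_index: int
    fold_gain: float = 84.0
    n_bps: int = 5
    wt_level: float = 0.2


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic regulome.

    Defaults mirror the emulated design: 200 genes, 20 processes, 3
    replicates per condition, 10% of genes differentially expressed at
    |log2FC| = 3 with 10% replicate CV, six planted complements with
    8-fold knockdown gain and 5 BP memberships, and 4 of the processes
    left uncovered by interacting proteins.
    """

    n_genes: int = 200
    n_bps: int = 20
    replicates: int = 3
    baseline_meanlog: float = 5.0  # log-scale mean of gene baselines
    baseline_sdlog: float = 1.0
    noise_cv: float = 0.10
    de_fraction: float = 0.10
    de_log2fc: float = 3.0
    complements: tuple[ComplementSpec, ...] = tuple(
        ComplementSpec(gene_index=i) for i in range(6)
    )
    n_ips: int = 10
    ip_coverage: float = 1.0  # fraction of the coverable BPs annotated
    k_uncovered: int = 4
    min_memberships: int = 1
    max_memberships: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.ip_coverage <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.k_uncovered > self.n_bps:
            raise ValueError("k_uncovered cannot exceed n_bps")
        for c in self.complements:
            if not 0 <= c.gene_index < self.n_genes:
                raise ValueError(f"complement index {c.gene_index} out of "
                                 "range")
            if c.n_bps > self.n_bps:
                raise ValueError("complement membership exceeds n_bps")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def bp_ids(self) -> list[str]:
        return [f"GO:{7000000 + i:07d}" for i in range(self.n_bps)]


@dataclass
class GroundTruth:
    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    complements: set[str] = field(default_factory=set)
    uncovered_bps: set[str] = field(default_factory=set)
    binder_peptides: set[str] = field(default_factory=set)
    itc_params: dict = field(default_factory=dict)

    @property
    def de_genes(self) -> set[str]:
        return self.de_up | self.de_down

    def to_dict(self) -> dict:
        return {
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "complements": sorted(self.complements),
            "uncovered_bps": sorted(self.uncovered_bps),
            "binder_peptides": sorted(self.binder_peptides),
            "itc_params": self.itc_params,
        }


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def _lognormal_noise(rng: np.random.Generator, cv: float,
                     shape) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=shape)


def _planted_assignments(cfg: SynthConfig, rng: np.random.Generator):
    """Split gene indices into complements, DE up/down and nulls."""
    comp_idx = [c.gene_index for c in cfg.complements]
    free = [i for i in range(cfg.n_genes) if i not in set(comp_idx)]
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = list(rng.choice(free, size=min(n_de, len(free)), replace=False))
    half = len(de_idx) // 2
    return comp_idx, de_idx[:half], de_idx[half:]


def gen_expression(cfg: SynthConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the 2-condition x replicate expression matrix.

    WT replicates are log-normal around per-gene baselines; KO replicates
    shift planted DE genes by ``2**(+/-de_log2fc)`` and planted complements
    by their fold gain.  Deterministic under (config, seed).
    """
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    genes = cfg.gene_ids()
    baselines = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog,
                              cfg.n_genes)
    comp_idx, up_idx, down_idx = _planted_assignments(cfg, rng)

    ko_mult = np.ones(cfg.n_genes)
    ko_mult[up_idx] = 2.0 ** cfg.de_log2fc
    ko_mult[down_idx] = 2.0 ** (-cfg.de_log2fc)
    for c in cfg.complements:
        baselines[c.gene_index] = c.wt_level
        ko_mult[c.gene_index] = c.fold_gain

    cols, data = [], []
    for r in range(cfg.replicates):
        cols.append(f"WT_{r + 1}")
        data.append(baselines *
                    _lognormal_noise(rng, cfg.noise_cv, cfg.n_genes))
    for r in range(cfg.replicates):
        cols.append(f"KO_{r + 1}")
        data.append(baselines * ko_mult *
                    _lognormal_noise(rng, cfg.noise_cv, cfg.n_genes))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    condition_of = {c: (WT if c.startswith(WT) else KO) for c in cols}

    truth = GroundTruth(
        de_up={genes[i] for i in up_idx},
        de_down={genes[i] for i in down_idx},
        complements={genes[i] for i in comp_idx},
    )
    return ExpressionMatrix(values, condition_of), truth


def gen_annotations(
    cfg: SynthConfig,
) -> tuple[AnnotationTable, IPAnnotationTable, GroundTruth]:
    """Simulate gene->BP and interacting-protein->BP annotation tables.

    Every gene gets a random number of BP memberships; planted complements
    get their configured (broader) membership count.  The IP table covers
    ``ip_coverage`` of the BPs except the ``k_uncovered`` designated ones,
    which no IP touches.
    """
    rng = _rng(cfg.seed, _STREAM_ANNOTATION)
    genes, bps = cfg.gene_ids(), cfg.bp_ids()
    comp_bps = {c.gene_index: c.n_bps for c in cfg.complements}
    rows = []
    for i, gene in enumerate(genes):
        k = comp_bps.get(
            i, int(rng.integers(cfg.min_memberships,
                                cfg.max_memberships + 1)))
        for term in rng.choice(bps, size=k, replace=False):
            rows.append((gene, term, f"process_{term[-4:]}"))
    ann = AnnotationTable(
        pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])
    )

    uncovered = set(rng.choice(bps, size=cfg.k_uncovered, replace=False))
    coverable = [b for b in bps if b not in uncovered]
    n_cover = int(round(cfg.ip_coverage * len(coverable)))
    covered = list(rng.choice(coverable, size=n_cover, replace=False)) \
        if n_cover else []
    ip_rows = []
    for j, term in enumerate(covered):
        # guarantee full coverage of the covered set, then add random extras
        ip = f"IP{j % cfg.n_ips:02d}"
        ip_rows.append((ip, term, f"process_{term[-4:]}"))
    for _ in range(cfg.n_ips * 2):
        if not covered:
            break
        ip = f"IP{int(rng.integers(cfg.n_ips)):02d}"
        term = str(rng.choice(covered))
        ip_rows.append((ip, term, f"process_{term[-4:]}"))
    ip_ann = IPAnnotationTable(
        pd.DataFrame(ip_rows, columns=["ip_id", "term_id", "term_name"])
    )
    truth = GroundTruth(uncovered_bps=uncovered)
    return ann, ip_ann, truth


def gen_dataset(cfg: SynthConfig):
    """Expression + annotations + merged ground truth in one call."""
    matrix, t_expr = gen_expression(cfg)
    ann, ip_ann, t_ann = gen_annotations(cfg)
    truth = GroundTruth(
        de_up=t_expr.de_up,
        de_down=t_expr.de_down,
        complements=t_expr.complements,
        uncovered_bps=t_ann.uncovered_bps,
    )
    return matrix, ann, ip_ann, truth


def gen_array(
    binders: Sequence[str],
    effect: float,
    noise_sd: float,
    seed: int,
    n_peptides: int = 20,
    n_empty: int = 8,
    replicates: int = 2,
    background: float = 100.0,
) -> tuple[PeptideArray, PeptideArray, GroundTruth]:
    """Simulate a test and a negative-control peptide array.

    Control spots fluoresce at ``background`` plus Gaussian noise; on the
    test array, binder peptides add ``effect`` RFU.  Both arrays include
    empty control spots at the background level.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng([seed, _STREAM_ARRAY])
    peptides = [f"pep{i:03d}" for i in range(n_peptides)]
    binder_set = set(binders) & set(peptides) if binders else set()
    if binders and not binder_set:
        binder_set = set(peptides[:len(list(binders))])

    def _spots(is_test: bool) -> pd.DataFrame:
        rows = []
        for pep in peptides:
            for r in range(replicates):
                rfu = background + rng.normal(0.0, noise_sd)
                if is_test and pep in binder_set:
                    rfu += effect
                rows.append((pep, r, max(rfu, 0.0), False))
        for e in range(n_empty):
            rows.append((f"empty{e:02d}", 0,
                         max(background + rng.normal(0.0, noise_sd), 0.0),
                         True))
        return pd.DataFrame(
            rows,
            columns=["peptide_id", "replicate", "rfu", "is_empty_control"],
        )

    test = PeptideArray(_spots(True), protein_label="test")
    control = PeptideArray(_spots(False), protein_label="control")
    return test, control, GroundTruth(binder_peptides=binder_set)


def gen_itc(
    ka: float,
    dh: float,
    n: float,
    p: ITCProtocol,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Single-site injection heats with additive Gaussian noise (ucal)."""
    heats = simulate_isotherm(ka, dh, n, p)
    if noise_sd > 0:
        rng = np.random.default_rng([seed, _STREAM_ITC])
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return heats
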