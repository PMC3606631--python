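"""End-to-end simulate -> genotype -> resolve -> estimate pipeline.

Used by the command-line interface and by the parameter-recovery checks:
a cohort is drawn from the catalog frequencies, peak observations are
generated with the assay forward model, copy numbers are re-derived from
the peaks, diplotypes resolved against the catalog and haplotype
frequencies re-estimated by EM.  With noiseless peaks the only information
loss is the genuine ambiguity of gene-content data (phase between the
centromeric and telomeric halves, del7 vs del8), which the EM resolves
statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .assays import expected_peaks, get_solver, integrate_assays
from .popgen import FrequencyEstimate, em_frequencies
from .reference import CatalogTable
from .resolve import DiploidResolution, resolve_genotype
from .simulate import SimulationConfig, realize_diplotype, sample_cohort, simulate_peaks


@dataclass
class PipelineResult:
    cohort: list
    resolutions: list[DiploidResolution]
    estimate: FrequencyEstimate
    n_failed: int = 0


def run_pipeline(catalog: CatalogTable, assays, n_individuals: int,
                 seed: int, sigma: float = 0.0,
                 frequency_table=None, em_tol: float = 1e-8,
                 em_max_iter: int = 1000) -> PipelineResult:
    """Full cohort pipeline; see module docstring.

    With ``sigma=0`` genotyping is deterministic per realized diplotype, so
    calls are cached by copy vector (the 2DS3/2DS5 realization of each
    2DS35 block is still drawn per sample).
    """
    cfg = SimulationConfig(n_individuals=n_individuals, seed=seed,
                           peak_noise_sigma=sigma,
                           frequency_table=frequency_table)
    cohort = sample_cohort(cfg, catalog)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    solver = get_solver(assays)
    cache: dict = {}
    resolutions = []
    n_failed = 0
    for sid, h1, h2 in cohort:
        try:
            if sigma == 0:
                dip = realize_diplotype(h1, h2, catalog, rng=rng,
                                        p_2DS3=cfg.p_2DS3)
                key = tuple(sorted(dip.items()))
                if key not in cache:
                    obs = [o for a in assays
                           for o in expected_peaks(dip, a, sample_id=sid)]
                    call = integrate_assays(obs, assays, solver=solver)
                    cache[key] = resolve_genotype(call, catalog)
                res = replace(cache[key], sample_id=sid)
            else:
                obs = simulate_peaks((h1, h2), assays, cfg, catalog,
                                     rng=rng, sample_id=sid)
                call = integrate_assays(obs, assays, solver=solver)
                res = resolve_genotype(call, catalog)
        except Exception:
            n_failed += 1
            continue
        resolutions.append(res)
    estimate = em_frequencies(resolutions, catalog, tol=em_tol,
                              max_iter=em_max_iter)
    return PipelineResult(cohort=cohort, resolutions=resolutions,
                          estimate=estimate, n_failed=n_failed)
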