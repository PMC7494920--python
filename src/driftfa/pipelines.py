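"""End-to-end analysis pipelines tying simulation, factor analysis and
ancestry estimation together.

These are the workflows behind the ``bench`` CLI subcommand and the
package's replication studies: analyze one admixture dataset with both
the drift-corrected factor model and the PC-projection baseline, or run
many seeded replicates and tabulate the errors.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

import driftfa as dfa


def analyze_admixture_dataset(
    ds,
    K: int = 2,
    lam="auto",
    grid=None,
    source_labels=("p1", "p2"),
    target_label: str = "adm",
):
    """Two-way ancestry of the admixed samples by FA and by PC projection.

    The factor model is fit jointly on all samples (row-centered), with
    the drift parameter auto-selected unless a float is given; ancestry is
    read from factor-1 positions relative to the source sample centers.
    The baseline builds principal components on the admixed (modern)
    samples only, projects the ancient sources, and applies the same
    center-based estimate.  Returns a dict with per-population estimates
    and the selected drift parameter.
    """
    g = ds.genotypes
    labels = ds.labels
    gc = dfa.center_rows(g)
    ts = dfa.transform_ages(ds.ages, gc)

    if lam == "auto":
        lam_val, res, _ = dfa.select_lambda(gc, ts, K, grid=grid)
    else:
        lam_val = float(lam)
        basis = dfa.spectral_basis(dfa.brownian_covariance(ts).C)
        res = dfa.fit_fa(gc, basis, dfa.FAConfig(K=K, lam=lam_val))

    ids = np.array(g.sample_ids)
    spec = dfa.SourceSpec(
        sources={
            source_labels[0]: list(ids[labels == source_labels[0]]),
            source_labels[1]: list(ids[labels == source_labels[1]]),
        },
        target=(target_label, list(ids[labels == target_label])),
    )
    u1 = pd.Series(res.scores[:, 0], index=ids)
    est_fa = dfa.two_way_ancestry(u1, spec)

    modern = labels == target_label
    est_pc = dfa.pc_projection_estimator(
        g.values[modern], g.values[~modern], spec, K,
        modern_ids=ids[modern], ancient_ids=ids[~modern],
    )
    return {
        "q_fa": float(est_fa.per_population.iloc[0]),
        "q_pc": float(est_pc.per_population.iloc[0]),
        "lam": lam_val,
        "est_fa": est_fa,
        "est_pc": est_pc,
        "result": res,
    }


def admixture_benchmark(
    scenario: str = "wf-admixture",
    replicates: int = 20,
    seed: int = 0,
    n_snps: int = 9600,
    admix_a: float = 0.75,
    lam="auto",
) -> pd.DataFrame:
    """Seeded replicates of the admixture scenario, FA vs PC projection.

    Returns one row per replicate with both population estimates and their
    squared errors against the simulated truth.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]
    for rep, s in enumerate(child_seeds):
        if scenario == "wf-admixture":
            ds = dfa.simulate_wf_serial(
                dfa.wf_admixture(admix_a=admix_a, n_snps=n_snps, seed=s)
            )
            src = ("p1", "p2")
        elif scenario == "admixture":
            ds = dfa.simulate_generative(
                dfa.admixture_scenario(admix_a=admix_a, p=n_snps, seed=s)
            )
            src = ("src1", "src2")
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        out = analyze_admixture_dataset(ds, lam=lam, source_labels=src)
        truth = ds.truth["admix_a"]
        rows.append(
            {
                "replicate": rep,
                "seed": s,
                "truth": truth,
                "q_fa": out["q_fa"],
                "q_pc": out["q_pc"],
                "lam": out["lam"],
                "fa_sq_err": (out["q_fa"] - truth) ** 2,
                "pc_sq_err": (out["q_pc"] - truth) ** 2,
            }
        )
    return pd.DataFrame(rows)


def single_population_check(seed: int = 0, n_snps: int = 9000, K: int = 2):
    """Horseshoe diagnostic on the single-population serial scenario.

    Returns the squared correlation of PC1 with time and the squared
    correlations of all K drift-corrected factors at the selected drift
    parameter.
    """
    ds = dfa.simulate_wf_serial(dfa.wf_single_population(n_snps=n_snps, seed=seed))
    gc = dfa.center_rows(ds.genotypes)
    ts = dfa.transform_ages(ds.ages, gc)
    U, s, _ = np.linalg.svd(gc.values, full_matrices=False)
    r2_pc1 = dfa.factor_time_association(U[:, 0] * s[0], ts.times)[0]
    lam, res, _ = dfa.select_lambda(gc, ts, K)
    r2_fa = [
        dfa.factor_time_association(res.U[:, k], ts.times)[0] for k in range(K)
    ]
    return {"r2_pc1": r2_pc1, "r2_fa": r2_fa, "lam": lam}
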