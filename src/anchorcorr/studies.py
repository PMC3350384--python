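"""Reference simulation studies exercising the full method.

These are the package's own benchmark experiments: seeded, deterministic
study designs used by the test suite and the reproduction script.  Each
returns plain dictionaries of measured quantities.

Problem sizes are chosen so every study runs in seconds to a few minutes
on one CPU: 13 datasets of ~5,000 genes x 100 samples for consensus
recovery, 200 replicates for test calibration, 1e5 draws for the
permutation oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .consensus import binomial_presence_pvalue, call_consensus, sharing_histogram
from .correlation import SelectionPolicy, correlate_anchor, select_candidates
from .diffexpr import anchor_diffexpr
from .io_formats import PathwayRecord
from .synthetic import SimulationConfig, simulate_dataset, simulate_collection

__all__ = [
    "consensus_recovery_study",
    "anchor_test_calibration",
    "exact_r_fixture",
    "fisher_z_vs_permutation",
    "null_correlation_uniformity",
    "worked_example_pathways",
]


def consensus_recovery_study(
    seed: int = 1234,
    n_background: int = 5000,
    n_planted: int = 50,
    n_per_class: int = 50,
    target_abs_r: float = 0.8,
) -> dict:
    """Plant-and-recover benchmark for the consensus caller.

    A 13-dataset collection (3/4/3/3 datasets for colon/liver/lung/
    thyroid, 100 samples each) carries ``n_planted`` genes at
    |r| = ``target_abs_r`` (70% positive, 30% negative) over
    ``n_background`` independent genes.  Candidates are selected by
    p < 0.001 alone (top fraction 1), the regime appropriate for a
    collection whose only truly correlated genes are the planted ones;
    consensus calls then use the presence >= 2 and |r| >= 0.6 rules.

    Returns per-tissue recovery fractions, the background call count and
    its binomial-null expectation, and the tissue-sharing histogram.
    """
    n_pos = int(round(0.7 * n_planted))
    planted = tuple(
        (f"PG{i:03d}", target_abs_r if i < n_pos else -target_abs_r)
        for i in range(n_planted)
    )
    config = SimulationConfig(
        n_genes=n_background,
        planted_genes=planted,
        n_samples={"cancer": n_per_class, "disease": 0, "normal": n_per_class},
        seed=seed,
    )
    datasets, truth = simulate_collection(config)
    policy = SelectionPolicy(
        p_cutoff=0.001,
        top_fraction={t: 1.0 for t in config.n_datasets_per_tissue},
    )
    from .preprocess import to_log2

    selected: dict[str, dict[str, list]] = {}
    for ds in datasets:
        records = correlate_anchor(to_log2(ds), config.anchor_symbol)
        records = select_candidates(records, policy, ds.metadata.tissue)
        selected.setdefault(ds.metadata.tissue, {})[ds.metadata.dataset_id] = records

    planted_set = {sym for sym, _ in planted}
    consensus_by_tissue = {}
    recovery = {}
    background_calls = 0
    expected_background = 0.0
    for tissue, per_dataset in sorted(selected.items()):
        calls = call_consensus(per_dataset, tissue, f=policy.p_cutoff)
        consensus_by_tissue[tissue] = calls
        called = {c.gene for c in calls}
        recovery[tissue] = len(called & planted_set) / len(planted_set)
        background_calls += len(called - planted_set)
        expected_background += n_background * binomial_presence_pvalue(
            2, len(per_dataset), policy.p_cutoff
        )
    return {
        "recovery_by_tissue": recovery,
        "min_recovery": min(recovery.values()),
        "background_calls": background_calls,
        "expected_background_calls": expected_background,
        "sharing": sharing_histogram(consensus_by_tissue),
        "consensus_by_tissue": consensus_by_tissue,
        "n_datasets": len(datasets),
        "truth": truth,
    }


def anchor_test_calibration(
    seed: int = 0,
    n_reps: int = 200,
    fold: float = 1.0,
    noise_sd: float = 0.5,
    n_per_class: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Replicated single-dataset significance rate of the anchor test.

    With fold 1.0 this measures the type-I error of the cancer-vs-normal
    comparison; with fold > 1 its power.  Each replicate is an
    independent simulated dataset.
    """
    k = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            n_genes=0,
            anchor_fold_change=fold,
            noise_sd=noise_sd,
            n_samples={"cancer": n_per_class, "disease": 0, "normal": n_per_class},
            output_scale="log2",
            seed=(seed * 100003 + rep) % (2**31 - 1),
        )
        ds, _ = simulate_dataset(config, dataset_id="cal01")
        res = anchor_diffexpr(ds, config.anchor_symbol, alpha=alpha)
        k += next(r.significant for r in res if r.comparison == "cancer_vs_normal")
    return {"n_significant": k, "n_reps": n_reps, "rate": k / n_reps}


def exact_r_fixture(n: int, r: float, rng: np.random.Generator):
    """Two vectors of length ``n`` whose sample Pearson r equals ``r``.

    Built by orthogonalizing a noise vector against the predictor and
    mixing on the unit sphere, so the comparison between analytic and
    permutation p-values is pinned to a known observed correlation.
    """
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    ec = e - e.mean()
    ec = ec - (ec @ xn) * xn
    en = ec / np.linalg.norm(ec)
    y = r * xn + np.sqrt(1 - r**2) * en
    return xn, y


def fisher_z_vs_permutation(
    seed: int = 5,
    n: int = 28,
    r_values: tuple[float, ...] = (0.2, 0.3, 0.45),
    n_perm: int = 100_000,
) -> list[dict]:
    """Fisher-z p-values against a seeded permutation oracle.

    Fixtures use moderate sample correlations, where the permutation
    null can resolve the p-value (>= 1/n_perm) and the normal
    approximation is in its accurate regime.
    """
    from .correlation import correlation_pvalue

    rng = np.random.default_rng(seed)
    out = []
    for r in r_values:
        xn, y = exact_r_fixture(n, r, rng)
        # y is centered with unit norm and stays so under permutation,
        # so each permuted correlation is a single dot product
        yc = y - y.mean()
        yn = yc / np.linalg.norm(yc)
        r_obs = float(yn @ xn)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        r_perm = yn[perms] @ xn
        p_perm = (np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1)
        p_z = correlation_pvalue(r_obs, n)
        out.append(
            {
                "r": r_obs,
                "p_fisher_z": p_z,
                "p_permutation": float(p_perm),
                "relative_error": abs(p_z - p_perm) / p_perm,
            }
        )
    return out


def null_correlation_uniformity(
    seed: int = 31, n_genes: int = 2000, n_per_class: int = 50
) -> dict:
    """KS uniformity check of Fisher-z p-values for independent genes."""
    config = SimulationConfig(
        n_genes=n_genes,
        anchor_fold_change=1.0,
        n_samples={"cancer": n_per_class, "disease": 0, "normal": n_per_class},
        output_scale="log2",
        seed=seed,
    )
    ds, _ = simulate_dataset(config, dataset_id="null01")
    records = correlate_anchor(ds, config.anchor_symbol)
    ps = np.array([rec.p_value for rec in records])
    ks = stats.kstest(ps, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue), "n": len(ps)}


def worked_example_pathways() -> list[PathwayRecord]:
    """A 207-pathway significant table with the canonical composition:
    20 cancer, 102 cancer-related (86 cell cycle + 9 apoptosis + 7 growth),
    85 other."""
    blocks = [
        (20, "ca", "carcinoma signature {i}"),
        (86, "cc", "mitotic spindle program {i}"),
        (9, "de", "apoptosis cascade {i}"),
        (7, "gr", "proliferation drive {i}"),
        (85, "ot", "metabolic route {i}"),
    ]
    records = []
    for count, prefix, template in blocks:
        for i in range(count):
            records.append(
                PathwayRecord(
                    name=f"{prefix}{i:03d}",
                    bio_function_terms=[template.format(i=i)],
                    genes=[f"{prefix.upper()}{i:03d}"],
                    p_value=0.001,
                )
            )
    return records
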