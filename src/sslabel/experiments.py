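"""Self-contained verification studies at desk scale.

Each function regenerates its inputs from a seed, runs the package's own
machinery, and returns the measured quantities.  They back both the
acceptance checks and the reproducibility script:

* CRF recursions vs exhaustive path enumeration;
* analytic NLL gradients vs central finite differences;
* the Q/Sov worked examples;
* the positional-encoding closed form;
* the synthetic Markov-corpus ablation study (full model vs no-CRF,
  Viterbi vs argmax forbidden-transition counts);
* end-to-end determinism of train -> predict -> evaluate.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .crf import CrfParameters, brute_force_oracle, log_partition, nll_gradients, nll_loss, viterbi_decode
from .encoding import positional_encoding
from .metrics import q_accuracy, sov
from .pipeline import RunConfig, evaluate, predict, train
from .synthetic import CorpusRecord, default_ss3_spec, generate_corpus

__all__ = [
    "crf_oracle_study", "crf_gradient_study", "metric_examples",
    "positional_encoding_error", "crf_ablation_study", "determinism_study",
]


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def crf_oracle_study(seed: int, n_instances: int = 200) -> Dict[str, float]:
    """Forward recursion and Viterbi vs exhaustive enumeration.

    Random instances with L <= 6 and K in {2, 3, 8}; returns the largest
    absolute discrepancies in log-partition, best-path score, and total
    path probability (which must be 1), plus the number of decoded paths
    that disagree with the enumerated argmax.
    """
    rng = np.random.default_rng(_derive_seed(seed, 1))
    max_logz_err = max_score_err = max_prob_err = 0.0
    path_mismatches = 0
    for _ in range(n_instances):
        K = int(rng.choice([2, 3, 8]))
        L = int(rng.integers(1, 7))
        em = 2.0 * rng.standard_normal((L, K))
        params = CrfParameters(
            2.0 * rng.standard_normal((K, K)),
            rng.standard_normal(K), rng.standard_normal(K),
        )
        scores, best_path, oracle_logz = brute_force_oracle(em, params)
        logz = log_partition(em, params)
        path, score = viterbi_decode(em, params)
        max_logz_err = max(max_logz_err, abs(logz - oracle_logz))
        max_score_err = max(max_score_err, abs(score - scores.max()))
        max_prob_err = max(max_prob_err, abs(np.exp(scores - logz).sum() - 1.0))
        path_mismatches += int(path != best_path)
    return {
        "log_partition_max_abs_err": max_logz_err,
        "viterbi_score_max_abs_err": max_score_err,
        "total_path_probability_max_abs_err": max_prob_err,
        "viterbi_path_mismatches": float(path_mismatches),
        "n": n_instances,
    }


def crf_gradient_study(seed: int, n_instances: int = 20,
                       step: float = 1e-5) -> Dict[str, float]:
    """Analytic NLL gradients vs central finite differences.

    Returns the worst relative error over all parameter blocks
    (emissions, transitions, start, stop) across random small instances.
    """
    rng = np.random.default_rng(_derive_seed(seed, 2))
    worst = 0.0
    for _ in range(n_instances):
        K = int(rng.choice([2, 3]))
        L = int(rng.integers(1, 7))
        em = rng.standard_normal((L, K))
        params = CrfParameters(rng.standard_normal((K, K)),
                               rng.standard_normal(K), rng.standard_normal(K))
        y = rng.integers(0, K, size=L)
        _, d_em, d_tr, d_st, d_sp = nll_gradients(em, y, params)
        blocks = {"em": (em, d_em), "tr": (params.transitions, d_tr),
                  "st": (params.start, d_st), "sp": (params.stop, d_sp)}
        for name, (arr, analytic) in blocks.items():
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + step
                hi = nll_loss(em, y, CrfParameters(
                    params.transitions, params.start, params.stop))
                arr[idx] = orig - step
                lo = nll_loss(em, y, CrfParameters(
                    params.transitions, params.start, params.stop))
                arr[idx] = orig
                fd[idx] = (hi - lo) / (2 * step)
            denom = max(np.abs(fd).max(), 1.0)
            worst = max(worst, np.abs(analytic - fd).max() / denom)
    return {"nll_gradient_max_rel_err": worst, "n": n_instances}


def metric_examples(seed: int, n_random: int = 100) -> Dict[str, float]:
    """The metric worked examples plus self-agreement on random labelings."""
    rng = np.random.default_rng(_derive_seed(seed, 3))
    self_sovs = []
    for _ in range(n_random):
        L = int(rng.integers(1, 60))
        y = "".join(rng.choice(list("HEC"), size=L))
        self_sovs.append(sov(y, y))
    return {
        "sov_self_agreement_min": float(min(self_sovs)),
        "sov_segment_example": sov("HHHHHCCC", "HHHCCCCC"),
        "q3_example": q_accuracy("HEC", "HEE"),
        "n": n_random,
    }


def positional_encoding_error(max_pos: int = 1000, d_model: int = 512) -> Dict[str, float]:
    """Worst deviation of the encoding from its closed form, plus the
    pos = 0 row pattern error."""
    pe = positional_encoding(max_pos + 1, d_model)
    pos = np.arange(max_pos + 1)[:, None]
    two_i = np.arange(0, d_model, 2)[None, :]
    angles = pos / 10000.0 ** (two_i / d_model)
    err = max(np.abs(pe[:, 0::2] - np.sin(angles)).max(),
              np.abs(pe[:, 1::2] - np.cos(angles)).max())
    row0 = max(np.abs(pe[0, 0::2]).max(), np.abs(pe[0, 1::2] - 1.0).max())
    return {"positional_encoding_max_abs_err": float(err),
            "position_zero_row_err": float(row0), "n": (max_pos + 1) * d_model}


def _held_out_accuracy(model, records: Sequence[CorpusRecord]) -> float:
    preds = predict(model, records)
    tot = hit = 0
    for r, p in zip(records, preds):
        tot += len(r.labels)
        hit += sum(a == b for a, b in zip(r.labels.labels, p.labels.labels))
    return 100.0 * hit / tot


def crf_ablation_study(seed: int, n_train: int = 200, n_test: int = 50,
                       epochs: int = 30) -> Dict[str, float]:
    """Train the full model and the no-CRF ablation on the Markov corpus.

    The corpus is the three-state spec with strong diagonal transitions
    and a forbidden helix-to-sheet move.  Reports held-out token accuracy
    for both models and the forbidden-adjacency counts of the full
    model's Viterbi decoding vs plain argmax of the same emissions.
    """
    train_recs = generate_corpus(default_ss3_spec(
        n_sequences=n_train, seed=_derive_seed(seed, 4)))
    test_recs = generate_corpus(default_ss3_spec(
        n_sequences=n_test, seed=_derive_seed(seed, 5)), id_prefix="tst")

    results: Dict[str, float] = {}
    full_model = None
    for label, use_crf in (("full_model_q3", True), ("no_crf_q3", False)):
        cfg = RunConfig.desk_scale(epochs=epochs, seed=_derive_seed(seed, 6),
                                   use_crf=use_crf)
        result = train(cfg, train_recs)
        # evaluate the best-validation checkpoint, as the train contract saves
        result.model.load_state_dict(result.best_state)
        results[label] = _held_out_accuracy(result.model, test_recs)
        if use_crf:
            full_model = result.model
    results["crf_margin_q3"] = results["full_model_q3"] - results["no_crf_q3"]

    params = full_model.crf_parameters()
    he_viterbi = he_argmax = 0
    for i in range(0, len(test_recs), 16):
        chunk = test_recs[i : i + 16]
        em, lengths = full_model.emissions(chunk)
        for b in range(len(chunk)):
            e = em.data[b, : lengths[b]]
            path_v, _ = viterbi_decode(e, params)
            path_a = np.argmax(e, axis=1)
            he_viterbi += "".join("HEC"[k] for k in path_v).count("HE")
            he_argmax += "".join("HEC"[int(k)] for k in path_a).count("HE")
    results["forbidden_adjacencies_viterbi"] = float(he_viterbi)
    results["forbidden_adjacencies_argmax"] = float(he_argmax)
    results["n"] = n_train
    return results


def determinism_study(seed: int, n_sequences: int = 60,
                      epochs: int = 5) -> Dict[str, float]:
    """Run train -> predict -> evaluate twice from one config and compare.

    Returns the largest absolute difference between the two evaluation
    reports (0 means bitwise-identical metric tables) and whether the
    predicted label strings match exactly.
    """
    spec = default_ss3_spec(n_sequences=n_sequences, seed=_derive_seed(seed, 8))
    reports, label_sets = [], []
    for _ in range(2):
        records = generate_corpus(spec)
        cfg = RunConfig.desk_scale(epochs=epochs, seed=_derive_seed(seed, 9))
        result = train(cfg, records)
        preds = predict(result.model, records)
        report = evaluate(preds, [(r.seq.id, r.labels) for r in records])
        reports.append(report)
        label_sets.append([p.labels.labels for p in preds])
    numeric = [r[["L", "Q", "Sov"]].to_numpy(dtype=float) for r in reports]
    return {
        "report_max_abs_diff": float(np.abs(numeric[0] - numeric[1]).max()),
        "predictions_identical": float(label_sets[0] == label_sets[1]),
        "n": n_sequences,
    }
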