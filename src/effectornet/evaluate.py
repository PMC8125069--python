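"""Scoring pipeline outputs against a synthetic community's ground truth."""

from __future__ import annotations

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .rhs import RhsArchitecture

__all__ = ["evaluate_recovery"]

#: truth kinds whose architecture, if recovered, should be orphan_toxin
_ORPHAN_KINDS = {"rhs_orphan", "t9ss_rhs", "t5ss_rhs"}


def _precision_recall(predicted: set, expected: set) -> tuple[float, float]:
    tp = len(predicted & expected)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(expected) if expected else 1.0
    return precision, recall


def evaluate_recovery(
    truth: pd.DataFrame,
    genome_truth: pd.DataFrame,
    architectures: dict[str, RhsArchitecture],
    vgrg_rows: list,
    verdicts: dict[str, str],
) -> dict:
    """Precision/recall per planted element kind, clustering agreement
    (adjusted Rand index against planted family labels), the T6SS verdict
    confusion matrix, and the DPxG split-position exact-match rate.

    Raises ``KeyError`` if outputs reference proteins absent from the
    truth ledger (an id-join error, not a biological disagreement).
    """
    known = set(truth["protein_id"])
    for pid in architectures:
        if pid not in known:
            raise KeyError(f"architecture for unknown protein {pid}")

    kind_of = dict(zip(truth["protein_id"], truth["kind"]))
    out: dict = {}

    # --- full-length vs orphan architecture labels -----------------------
    pred_full = {pid for pid, a in architectures.items()
                 if a.status == "full_length"}
    pred_orphan = {pid for pid, a in architectures.items()
                   if a.status == "orphan_toxin"}
    true_full = set(truth.loc[truth["kind"] == "rhs_full", "protein_id"])
    true_orphan = set(truth.loc[truth["kind"].isin(_ORPHAN_KINDS),
                                "protein_id"])
    out["full_length_precision"], out["full_length_recall"] = \
        _precision_recall(pred_full, true_full)
    out["orphan_precision"], out["orphan_recall"] = \
        _precision_recall(pred_orphan, true_orphan)

    # --- toxin-domain clustering vs planted families ---------------------
    def toxin_family(row) -> str | None:
        if row["kind"] == "rhs_full":
            return row["family"].split("/")[1]
        if row["kind"] in _ORPHAN_KINDS:
            return row["family"]
        return None

    fam_by_pid = {row["protein_id"]: toxin_family(row)
                  for _, row in truth.iterrows()}
    pred_labels, true_labels = [], []
    for pid, a in sorted(architectures.items()):
        fam = fam_by_pid.get(pid)
        if fam is not None and a.toxin_cluster is not None:
            pred_labels.append(a.toxin_cluster)
            true_labels.append(fam)
    out["toxin_cluster_ari"] = (
        float(adjusted_rand_score(true_labels, pred_labels))
        if true_labels else 1.0)
    out["n_toxin_clusters"] = len({a.toxin_cluster
                                   for a in architectures.values()
                                   if a.toxin_cluster})
    # false assignments: decoys or unrelated proteins given a toxin cluster
    toxin_pids = {pid for pid, fam in fam_by_pid.items() if fam is not None}
    out["toxin_false_assignments"] = sum(
        1 for pid, a in architectures.items()
        if a.toxin_cluster and pid not in toxin_pids)

    # --- VgrG clustering --------------------------------------------------
    vgrg_kinds = {"vgrg", "vgrg_pseudo", "vgrg_fragment"}
    vfam = {row["protein_id"]: row["family"] for _, row in truth.iterrows()
            if row["kind"] in vgrg_kinds}
    vp, vt = [], []
    v_false = 0
    for r in sorted(vgrg_rows, key=lambda r: r.protein_id):
        fam = vfam.get(r.protein_id)
        if fam is None:
            v_false += 1
            continue
        vp.append(r.cluster_id)
        vt.append(fam)
    out["vgrg_cluster_ari"] = (float(adjusted_rand_score(vt, vp))
                               if vt else 1.0)
    out["n_vgrg_clusters"] = len({r.cluster_id for r in vgrg_rows})
    out["vgrg_false_assignments"] = v_false
    true_pseudo = set(truth.loc[truth["kind"] == "vgrg_pseudo",
                                "protein_id"])
    pred_trunc = {r.protein_id for r in vgrg_rows if r.truncated_flag}
    out["pseudo_precision"], out["pseudo_recall"] = \
        _precision_recall(pred_trunc, true_pseudo)

    # --- T6SS verdicts ----------------------------------------------------
    confusion: dict[tuple[str, str], int] = {}
    correct = 0
    for _, row in genome_truth.iterrows():
        intended = row["intended_verdict"]
        got = verdicts.get(row["genome_id"], "absent")
        confusion[(intended, got)] = confusion.get((intended, got), 0) + 1
        correct += intended == got
    out["t6ss_confusion"] = {f"{a}->{b}": n
                             for (a, b), n in sorted(confusion.items())}
    out["t6ss_verdict_accuracy"] = (correct / len(genome_truth)
                                    if len(genome_truth) else 1.0)

    # --- DPxG split positions --------------------------------------------
    split_truth = truth.loc[truth["kind"] == "rhs_full",
                            ["protein_id", "split_pos"]]
    n_checked = n_exact = n_checked_unique = n_exact_unique = 0
    for _, row in split_truth.iterrows():
        a = architectures.get(row["protein_id"])
        if a is None or a.toxin_span is None:
            continue
        exact = a.toxin_span[0] == row["split_pos"]
        n_checked += 1
        n_exact += exact
        if not a.ambiguous_split:
            n_checked_unique += 1
            n_exact_unique += exact
    out["split_match_rate"] = n_exact / n_checked if n_checked else 1.0
    out["split_match_rate_unique"] = (n_exact_unique / n_checked_unique
                                      if n_checked_unique else 1.0)
    out["n_splits_checked"] = n_checked
    return out
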