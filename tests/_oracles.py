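"""Independent reference implementations used only as test oracles."""

import numpy as np

NEG = -1e18


def affine_dp_score(target: str, query: str, match=2.0, mismatch=-4.0,
                    gap_open=6.0, gap_extend=1.0) -> float:
    """Exhaustive Gotoh DP score: global in the query, free target end gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  Row-wise dynamic
    programme with three states: M (query base aligned to target base),
    I (query base against a gap), D (target base against a gap, internal
    only; end deletions are free via the initialisation and final maximum).
    """
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    m, n = len(q), len(t)
    go, ge = gap_open, gap_extend
    j_idx = np.arange(n + 1)

    # prev_any[j]: best score of any alignment state after consuming
    # query[:i-1] and target[:j].  Row 0 is all zeros: the leading target
    # overhang is free.
    prev_any = np.zeros(n + 1)
    I_prev = np.full(n + 1, NEG)

    M_cur = I_cur = D_cur = None
    for i in range(1, m + 1):
        s = np.where(t == q[i - 1], match, mismatch)
        M_cur = np.full(n + 1, NEG)
        M_cur[1:] = prev_any[:-1] + s
        # query base against a gap: open from any state, extend from I
        I_cur = np.maximum(prev_any - go - ge, I_prev - ge)
        # target base against a gap (internal deletion), same row:
        # D[j] = max_{k<j} max(M, I)[k] - go - (j - k) * ge
        base = np.maximum(M_cur, I_cur) + j_idx * ge
        D_cur = np.full(n + 1, NEG)
        D_cur[1:] = np.maximum.accumulate(base[:-1]) - go - j_idx[1:] * ge
        prev_any = np.maximum.reduce([M_cur, I_cur, D_cur])
        I_prev = I_cur

    # free trailing target gap: take the best over all target prefixes
    return float(prev_any.max())


def affine_dp_score_both(target: str, query: str, **kw) -> float:
    """Best score over both read orientations, as the pipeline aligner uses."""
    comp = str.maketrans("ACGTN", "TGCAN")
    return max(affine_dp_score(target, query, **kw),
               affine_dp_score(target, query.translate(comp)[::-1], **kw))


def classify_brute_force(allele_seq: str, protospacer_ref: str,
                         intended_positions, substrate: str, product: str,
                         indel: bool) -> str:
    """Direct rule evaluation of the allele classes on explicit sequences."""
    if indel:
        return "indel_allele"
    assert len(allele_seq) == len(protospacer_ref)
    if allele_seq == protospacer_ref:
        return "unedited"
    perfect = list(protospacer_ref)
    for p in intended_positions:
        assert perfect[p - 1] == substrate
        perfect[p - 1] = product
    if intended_positions and allele_seq == "".join(perfect):
        return "perfect"
    return "imperfect_edit"


def permutation_t_pvalue(x, y, n_perm=20000, seed=0) -> float:
    """Two-sided permutation p-value for the difference of group means."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    nx = len(x)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        hits += abs(pooled[:nx].mean() - pooled[nx:].mean()) >= obs - 1e-12
    return hits / n_perm
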