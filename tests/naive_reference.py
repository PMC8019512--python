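"""Independent, loop-based reference implementations used as test oracles.

Everything here is written as plainly as possible — explicit Python loops
over variables, components and blocks, and the residual-subtraction form of
the explained sum of squares — deliberately avoiding the vectorized paths of
the package so the two routes are independent.
"""

import math

import numpy as np


def naive_ssd(D, t):
    """Explained SS as SS(D) - SS(D - t p_hat^T) with the least-squares loading."""
    D = np.asarray(D, float)
    t = np.asarray(t, float)
    p_hat = D.T @ t / (t @ t)
    resid = D - np.outer(t, p_hat)
    return float(np.sum(D**2) - np.sum(resid**2))


def naive_ssd_table(model, dataset):
    ssd = {}
    for a, comp in enumerate(model.components):
        for d in comp.member_blocks:
            ssd[(comp.component_id, d)] = naive_ssd(
                dataset.blocks[d], model.scores[:, a]
            )
    ssd_cum = {}
    ss_total = {}
    for d in range(dataset.n_blocks):
        total = 0.0
        for (cid, dd), value in ssd.items():
            if dd == d:
                total += value
        ssd_cum[d] = total
        ss_total[d] = float(np.sum(np.asarray(dataset.blocks[d]) ** 2))
    return ssd, ssd_cum, ss_total


def _normalize(raw, K):
    norm = math.sqrt(sum(x * x for x in raw))
    if norm == 0.0:
        return [0.0] * K
    return [math.sqrt(K) * x / norm for x in raw]


def naive_profiles(model, dataset, cumulative="explained"):
    """Per-element evaluation of the four importance profiles per block.

    Returns {(block, kind): list of floats}; empty profiles are zero lists.
    """
    ssd, ssd_cum, ss_total = naive_ssd_table(model, dataset)
    denom = ssd_cum if cumulative == "explained" else ss_total
    out = {}
    for d in range(dataset.n_blocks):
        K = dataset.blocks[d].shape[1]

        raw_u = []
        for k in range(K):
            s = 0.0
            for comp in model.components:
                if comp.kind == "unique" and d in comp.member_blocks:
                    p = model.loadings[(comp.component_id, d)]
                    s += p[k] ** 2 * ssd[(comp.component_id, d)] / denom[d]
            raw_u.append(math.sqrt(s))
        out[(d, "unique")] = _normalize(raw_u, K)

        beta = 0
        for comp in model.components:
            if comp.kind == "local" and d in comp.member_blocks:
                beta += len(comp.member_blocks) - 1
        raw_l = []
        for k in range(K):
            s = 0.0
            for comp in model.components:
                if comp.kind == "local" and d in comp.member_blocks:
                    p = model.loadings[(comp.component_id, d)]
                    for d_lc in comp.member_blocks:
                        if d_lc == d:
                            continue
                        s += (
                            p[k] ** 2
                            * ssd[(comp.component_id, d_lc)]
                            / denom[d_lc]
                        )
            raw_l.append(math.sqrt(s / beta) if beta else 0.0)
        out[(d, "local")] = _normalize(raw_l, K)

        raw_g = []
        for k in range(K):
            s = 0.0
            for comp in model.components:
                if comp.kind == "global":
                    p = model.loadings[(comp.component_id, d)]
                    for d_j in comp.member_blocks:
                        s += p[k] ** 2 * ssd[(comp.component_id, d_j)] / denom[d_j]
            raw_g.append(math.sqrt(s))
        out[(d, "global")] = _normalize(raw_g, K)

        raw_t = [
            math.sqrt(
                out[(d, "unique")][k] ** 2
                + out[(d, "local")][k] ** 2
                + out[(d, "global")][k] ** 2
            )
            for k in range(K)
        ]
        out[(d, "total")] = _normalize(raw_t, K)
    return out
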