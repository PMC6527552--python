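"""Numba kernel for the collapsed Gibbs sampler.

Kept separate so the compiled kernel stays a pure function of primitive
arrays: token stream in, final (and optionally averaged) assignment counts
out. Seeding uses numba's internal PRNG, so a fixed seed gives bit-identical
chains across runs and platforms.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def run_gibbs(doc_ids, word_ids, n_docs, n_words, n_topics,
              alpha, beta, n_iter, burn_in, seed, average):
    """Collapsed Gibbs over token-level topic assignments.

    Returns (ndk, nkw, ndk_sum, nkw_sum, n_samples): final doc-topic and
    topic-word counts, plus post-burn-in accumulators when ``average``.
    """
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    ndk = np.zeros((n_docs, n_topics), dtype=np.int64)
    nkw = np.zeros((n_topics, n_words), dtype=np.int64)
    nk = np.zeros(n_topics, dtype=np.int64)
    for t in range(n_tokens):
        k = np.int64(np.random.random() * n_topics)
        if k == n_topics:
            k = n_topics - 1
        z[t] = k
        ndk[doc_ids[t], k] += 1
        nkw[k, word_ids[t]] += 1
        nk[k] += 1
    ndk_sum = np.zeros((n_docs, n_topics), dtype=np.float64)
    nkw_sum = np.zeros((n_topics, n_words), dtype=np.float64)
    n_samples = 0
    cum = np.empty(n_topics, dtype=np.float64)
    vbeta = n_words * beta
    for it in range(n_iter):
        for t in range(n_tokens):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
                cum[kk] = total
            u = np.random.random() * total
            k = n_topics - 1
            for kk in range(n_topics):
                if u < cum[kk]:
                    k = kk
                    break
            z[t] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1
        if average and it >= burn_in:
            ndk_sum += ndk
            nkw_sum += nkw
            n_samples += 1
    return ndk, nkw, ndk_sum, nkw_sum, n_samples
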