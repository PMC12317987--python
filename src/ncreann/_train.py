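"""Numba kernel for incremental error-back-propagation with momentum.

One call performs one epoch: a pass over the training rows in the given
order, updating the weights after every sample (incremental / online EBP).
The network is a single-hidden-layer perceptron,
``yhat = W2 @ act(W1 @ x + b1) + b2`` with act either tanh or identity.
Gradients are of the per-sample squared error 0.5 * ||yhat - y||^2.
Explicit loops keep the kernel allocation-free; the matrices involved are
tiny (H ~ 10, M*p ~ 10), so per-sample cost is a few hundred flops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ACT_TANH = 0
ACT_IDENTITY = 1


@njit(cache=False, fastmath=False)
def epoch_pass(
    X, Y, order,
    W1, b1, W2, b2,
    vW1, vb1, vW2, vb2,
    lr, momentum, act_id,
):  # pragma: no cover - exercised through fit_ncreann
    H, D = W1.shape
    M = W2.shape[0]
    h = np.empty(H)
    e = np.empty(M)
    dpre = np.empty(H)
    for idx in range(order.shape[0]):
        t = order[idx]
        x = X[t]
        y = Y[t]
        # forward
        for k in range(H):
            acc = b1[k]
            for d in range(D):
                acc += W1[k, d] * x[d]
            h[k] = np.tanh(acc) if act_id == ACT_TANH else acc
        for j in range(M):
            acc = b2[j]
            for k in range(H):
                acc += W2[j, k] * h[k]
            e[j] = acc - y[j]
        # hidden deltas from the pre-update output weights
        for k in range(H):
            acc = 0.0
            for j in range(M):
                acc += W2[j, k] * e[j]
            if act_id == ACT_TANH:
                acc *= 1.0 - h[k] * h[k]
            dpre[k] = acc
        # output layer update
        for j in range(M):
            ej = e[j]
            for k in range(H):
                vW2[j, k] = momentum * vW2[j, k] - lr * ej * h[k]
                W2[j, k] += vW2[j, k]
            vb2[j] = momentum * vb2[j] - lr * ej
            b2[j] += vb2[j]
        # hidden layer update
        for k in range(H):
            dk = dpre[k]
            for d in range(D):
                vW1[k, d] = momentum * vW1[k, d] - lr * dk * x[d]
                W1[k, d] += vW1[k, d]
            vb1[k] = momentum * vb1[k] - lr * dk
            b1[k] += vb1[k]
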