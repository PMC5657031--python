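"""Independent single-machine reference implementations used as test oracles.

These deliberately re-derive each algorithm from its mathematical definition
(plain numpy loops, no shared code paths with the package) so that agreement
between a decentralized run and its oracle is evidence, not tautology.
"""

import numpy as np

from consortium_lite._utils import derive_site_seed


def centralized_gd_oracle(X_raw, y_raw, lam, lr, max_iter, tol):
    """Pooled gradient descent for ridge regression with the same schedule:

    standardize X and y by global moments, descend from zero with objective
    backtracking (halve the step on increase, 1e-12 relative slack), return
    (iterate sequence on the standardized scale, final accepted iterate).
    """
    mx, sx = X_raw.mean(axis=0), X_raw.std(axis=0)
    sx[sx == 0] = 1.0
    my, sy = y_raw.mean(), y_raw.std() or 1.0
    X = np.column_stack([np.ones(len(y_raw)), (X_raw - mx) / sx])
    y = (y_raw - my) / sy
    n, k = X.shape
    w = np.zeros(k)
    prev = None
    iterates = [w.copy()]
    for _ in range(max_iter):
        w_pen = w.copy()
        w_pen[0] = 0.0
        grad = (-2.0 * X.T @ (y - X @ w) + 2.0 * lam * w_pen) / n
        obj = float((y - X @ w) @ (y - X @ w)) + lam * float(w_pen @ w_pen)
        if prev is None or obj <= prev[2] * (1.0 + 1e-12):
            prev = (w.copy(), grad.copy(), obj)
            if np.linalg.norm(grad) < tol:
                break
            w = w - lr * grad
        else:
            lr *= 0.5
            w = prev[0] - lr * prev[1]
        iterates.append(w.copy())
    return iterates, prev[0]


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def reference_forward_backward(layers, x, y):
    """Plain softmax-output MLP loss/gradient for one sample."""
    acts = [x]
    for li, (W, b) in enumerate(layers):
        z = W @ acts[-1] + b
        if li == len(layers) - 1:
            e = np.exp(z - z.max())
            acts.append(e / e.sum())
        else:
            acts.append(sigmoid(z))
    loss = -float((y * np.log(acts[-1])).sum())
    delta = acts[-1] - y
    grads = [None] * len(layers)
    for li in range(len(layers) - 1, -1, -1):
        grads[li] = (np.outer(delta, acts[li]), delta.copy())
        if li > 0:
            delta = (layers[li][0].T @ delta) * acts[li] * (1 - acts[li])
    return loss, grads


def centralized_minibatch_oracle(site_data, architecture, lr, epochs, master_seed):
    """Pooled mini-batch SGD whose batches are the same one-sample-per-site
    groups, assembled with the same per-site shuffled orders."""
    from consortium_lite.neuralnet import init_mlp

    layers = [
        (W.copy(), b.copy()) for W, b in init_mlp(architecture, seed=master_seed).layers
    ]
    orders = {}
    rngs = {
        sid: np.random.default_rng(derive_site_seed(master_seed, i))
        for i, (sid, _, _) in enumerate(site_data)
    }
    pos = {sid: 0 for sid, _, _ in site_data}
    rounds = max(len(y) for _, _, y in site_data) * epochs
    for _ in range(rounds):
        grads_sum = None
        for sid, X, y in site_data:
            if sid not in orders or pos[sid] >= len(orders[sid]):
                orders[sid] = rngs[sid].permutation(len(y))
                pos[sid] = 0
            idx = orders[sid][pos[sid]]
            pos[sid] += 1
            onehot = np.zeros(architecture[-1])
            onehot[int(y[idx])] = 1.0
            _, g = reference_forward_backward(layers, X[idx], onehot)
            if grads_sum is None:
                grads_sum = [[gW, gb] for gW, gb in g]
            else:
                for acc, (gW, gb) in zip(grads_sum, g):
                    acc[0] = acc[0] + gW
                    acc[1] = acc[1] + gb
        n = len(site_data)
        layers = [
            (W - lr * gW / n, b - lr * gb / n)
            for (W, b), (gW, gb) in zip(layers, grads_sum)
        ]
    return layers


def pooled_infomax_oracle(X_pooled, rho, n_iter):
    """Plain pooled natural-gradient Infomax on whitened channels x samples data,
    with the same entropy-backtracking step rule."""
    m, n = X_pooled.shape
    mean = X_pooled.mean(axis=1, keepdims=True)
    cov = np.cov(X_pooled, bias=True)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    V = (vecs[:, order] / np.sqrt(vals[order])).T
    Xw = V @ (X_pooled - mean)
    W, b = np.eye(m), np.zeros(m)
    prev = None
    for _ in range(n_iter):
        Z = W @ Xw + b[:, None]
        Y = 1.0 / (1.0 + np.exp(-Z))
        U = 1.0 - 2.0 * Y
        G = (n * np.eye(m) + U @ Z.T) @ W
        h = U.sum(axis=1)
        obj = np.linalg.slogdet(W)[1] + np.log(np.maximum(Y * (1 - Y), 1e-300)).sum() / n
        if prev is None or obj >= prev[4]:
            prev = (W.copy(), b.copy(), G, h, obj)
            W = W + rho * G / n
            b = b + rho * h / n
        else:
            rho *= 0.5
            W = prev[0] + rho * prev[2] / n
            b = prev[1] + rho * prev[3] / n
    return prev[0] @ V, V
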