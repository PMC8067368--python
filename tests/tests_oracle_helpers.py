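"""Shared independent oracles used by several test modules.

The loop-based forward oracle evaluates the sub-model equations directly —
scalar convolution sums, the divisor-form LeakyReLU, the affine sigmoid
output — without any of the vectorized machinery of the implementation.
"""

import numpy as np


def loop_forward_oracle(model, X_sub):
    """Direct per-sample, per-position evaluation of the network in
    inference mode (stored running batch-norm statistics)."""
    cfg = model.config
    a = cfg.leaky_divisor
    P = (cfg.kernel_size - 1) // 2
    preds = []
    for row in np.atleast_2d(X_sub):
        h = row[None, :].astype(float)              # (channels, length)
        for l in range(cfg.n_conv_layers):
            mean, var = model.bn_running[l]
            gamma = model.params["bn_gamma"][l]
            beta = model.params["bn_beta"][l]
            hn = np.empty_like(h)
            for c in range(h.shape[0]):
                hn[c] = gamma[c] * (h[c] - mean[c]) \
                    / np.sqrt(var[c] + 1e-5) + beta[c]
            W = model.params["conv_W"][l]
            b = model.params["conv_b"][l]
            F, C, K = W.shape
            L = h.shape[1]
            hp = np.zeros((C, L + 2 * P))
            hp[:, P:P + L] = hn
            out = np.zeros((F, L))
            for f in range(F):
                for i in range(L):
                    acc = b[f]
                    for c in range(C):
                        for k in range(K):
                            acc += hp[c, i + k] * W[f, c, k]
                    out[f, i] = acc if acc > 0 else acc / a
            h = out
        flat = h.T.reshape(-1)  # position-major, channel-minor flattening
        logit = flat @ model.params["out_w"] + model.params["out_b"][0]
        preds.append(1.0 / (1.0 + np.exp(-logit)))
    return np.array(preds)
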