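"""Independent loop-level reference implementations used as test oracles.

Everything here is deliberately written as plain Python loops over scalars,
sharing no code with the package's vectorized implementations.
"""

import math

import numpy as np


def sigmoid_scalar(v: float) -> float:
    if v >= 0:
        return 1.0 / (1.0 + math.exp(-v))
    e = math.exp(v)
    return e / (1.0 + e)


def cam_oracle(Y, p, gate="literal"):
    """Channel attention: pooled stats -> shared bottleneck -> residual gate."""
    Y = np.asarray(Y, dtype=float)
    c, length = Y.shape
    z_avg = [sum(Y[i, j] for j in range(length)) / length for i in range(c)]
    z_max = [max(Y[i, j] for j in range(length)) for i in range(c)]
    w1, b1 = np.asarray(p.reduce_weights), np.asarray(p.reduce_bias)
    w2, b2 = np.asarray(p.expand_weights), np.asarray(p.expand_bias)
    hidden = w1.shape[0]

    def branch(z):
        h = []
        for r in range(hidden):
            acc = b1[r]
            for i in range(c):
                acc += w1[r, i] * z[i]
            h.append(max(acc, 0.0))
        out = []
        for i in range(c):
            acc = b2[i]
            for r in range(hidden):
                acc += w2[i, r] * h[r]
            out.append(acc)
        return out

    bm, ba = branch(z_max), branch(z_avg)
    if gate == "literal":
        z_star = [sigmoid_scalar(bm[i]) + sigmoid_scalar(ba[i]) for i in range(c)]
    else:
        z_star = [sigmoid_scalar(bm[i] + ba[i]) for i in range(c)]
    out = np.empty_like(Y)
    for i in range(c):
        for j in range(length):
            out[i, j] = Y[i, j] + Y[i, j] * z_star[i]
    return out, np.array(z_star)


def sam_oracle(Y, p):
    """Spectral attention: per-position ReLU(w . y_j + b), residual gate."""
    Y = np.asarray(Y, dtype=float)
    c, length = Y.shape
    w = np.asarray(p.weights).reshape(-1)
    b = float(np.asarray(p.bias))
    t_star = []
    for j in range(length):
        acc = b
        for i in range(c):
            acc += w[i] * Y[i, j]
        t_star.append(max(acc, 0.0))
    out = np.empty_like(Y)
    for i in range(c):
        for j in range(length):
            out[i, j] = Y[i, j] + t_star[j] * Y[i, j]
    return out, np.array(t_star)


def csam_oracle(Y, cam_p, sam_p, gate="literal"):
    mid, _ = sam_oracle(Y, sam_p)
    out, _ = cam_oracle(mid, cam_p, gate=gate)
    return out


def metrics_oracle(y_pred, y_true, n_classes):
    """Naive per-sample counting: (accuracy, macro precision, macro sensitivity) %."""
    n = len(y_true)
    correct = sum(1 for p, t in zip(y_pred, y_true) if p == t)
    precs, senss = [], []
    for c in range(n_classes):
        tp = sum(1 for p, t in zip(y_pred, y_true) if p == c and t == c)
        fp = sum(1 for p, t in zip(y_pred, y_true) if p == c and t != c)
        fn = sum(1 for p, t in zip(y_pred, y_true) if p != c and t == c)
        precs.append(100.0 * tp / (tp + fp) if tp + fp else 0.0)
        senss.append(100.0 * tp / (tp + fn) if tp + fn else 0.0)
    return (100.0 * correct / n, sum(precs) / n_classes, sum(senss) / n_classes)


def conv_block_oracle(block, params, x, cam_reduction=4, gate="literal"):
    """Loop-level eval-mode conv block: BN -> conv -> ReLU -> maxpool -> attention."""
    x = np.asarray(x, dtype=float)
    c_in, length = x.shape
    eps = 1e-5
    if block.batch_norm_before:
        g, b = params["bn.gamma"], params["bn.beta"]
        rm, rv = params["bn.running_mean"], params["bn.running_var"]
        out = np.empty_like(x)
        for i in range(c_in):
            for j in range(length):
                out[i, j] = g[i] * (x[i, j] - rm[i]) / math.sqrt(rv[i] + eps) + b[i]
        x = out
    w, bias = params["conv.w"], params["conv.b"]
    c_out, _, k = w.shape
    pad = (k - 1) // 2 if block.padded else 0
    xp = np.zeros((c_in, length + 2 * pad))
    xp[:, pad:pad + length] = x
    l_conv = xp.shape[1] - k + 1
    y = np.empty((c_out, l_conv))
    for o in range(c_out):
        for j in range(l_conv):
            acc = bias[o]
            for i in range(c_in):
                for kk in range(k):
                    acc += w[o, i, kk] * xp[i, j + kk]
            y[o, j] = max(acc, 0.0)                    # ReLU activation
    if block.pool == "max":
        l_out = l_conv // block.pool_kernel
        pooled = np.empty((c_out, l_out))
        for o in range(c_out):
            for j in range(l_out):
                lo = j * block.pool_stride
                pooled[o, j] = max(y[o, lo:lo + block.pool_kernel])
        y = pooled
    if block.attention_after == "cam":
        from specattn.attention import CamParams
        y, _ = cam_oracle(y, CamParams(params["cam.w1"], params["cam.b1"],
                                       params["cam.w2"], params["cam.b2"],
                                       cam_reduction), gate)
    elif block.attention_after == "sam":
        from specattn.attention import SamParams
        y, _ = sam_oracle(y, SamParams(params["sam.w"], params["sam.b"]))
    elif block.attention_after == "csam":
        from specattn.attention import CamParams, SamParams
        y = csam_oracle(y, CamParams(params["cam.w1"], params["cam.b1"],
                                     params["cam.w2"], params["cam.b2"],
                                     cam_reduction),
                        SamParams(params["sam.w"], params["sam.b"]), gate)
    return y


def model_oracle(spec, params, spectrum):
    """Layer-by-layer eval-mode pass over one spectrum -> class probabilities."""
    x = np.asarray(spectrum, dtype=float)[None, :]     # 1 channel x bands
    for i, block in enumerate(spec.blocks):
        local = {k[len(f"block{i}."):]: v for k, v in params.items()
                 if k.startswith(f"block{i}.")}
        x = conv_block_oracle(block, local, x, spec.cam_reduction, spec.cam_gate)
    v = [x[i, j] for i in range(x.shape[0]) for j in range(x.shape[1])]
    n_layers = len(spec.fc_sizes)
    for layer in range(n_layers):
        w, b = params[f"fc{layer}.w"], params[f"fc{layer}.b"]
        out = []
        for o in range(w.shape[1]):
            acc = b[o]
            for i in range(w.shape[0]):
                acc += w[i, o] * v[i]
            out.append(acc if layer == n_layers - 1 else max(acc, 0.0))
        v = out
    mx = max(v)
    e = [math.exp(z - mx) for z in v]
    s = sum(e)
    return np.array([ei / s for ei in e])
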