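"""A compact non-local CNN + GCN node classifier in NumPy.

Architecture: two strided convolutions over the oriented patch planes, one
embedded-Gaussian self-attention (non-local) block over the spatial feature
map, radial-zone average pooling into a feature vector Y = Phi(P|theta)
(the discriminative structure sits at a radius from the vessel axis, so
concentric zones preserve it where a global mean would not), then a
two-layer graph convolution H' = sigma(W H Theta) over the star graph of a
center node and its sampled neighbors, with the center row's logits trained
by cross-entropy.  All gradients are written by hand and verified by finite
differences in the test suite; SGD with momentum does the updates.

The network is deliberately small: it runs on a single CPU core at desk
scale, which is all the synthetic experiments require.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float64


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, outH*outW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]
    out_h, out_w = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w, c * k * k)
    return np.ascontiguousarray(cols), (out_h, out_w)


def col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of im2col: scatter column gradients back to the input grid."""
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, out_h, out_w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * out_h:stride, j:j + stride * out_w:stride] += (
                d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return dxp[:, :, pad:pad + h, pad:pad + w]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x - x.max(axis=axis, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=axis, keepdims=True)


class NonLocalGCNClassifier:
    """Phi (non-local CNN) + 2-layer GCN over [center, neighbors] stars."""

    def __init__(
        self,
        in_channels: int,
        patch_planes: int = 3,
        conv_channels=(8, 16),
        attention_dim: int = 8,
        feature_dim: int = 16,
        gcn_hidden: int = 16,
        n_neighbors: int = 2,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.planes = patch_planes
        self.c1, self.c2 = conv_channels
        self.da = attention_dim
        self.fdim = feature_dim
        self.hidden = gcn_hidden
        self.m = n_neighbors
        rng = np.random.default_rng(seed)

        def init(*shape):
            fan_in = shape[0]
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)

        cin = in_channels * patch_planes
        self.params = {
            "W1": init(cin * 25, self.c1), "b1": np.zeros(self.c1, DTYPE),
            "W2": init(self.c1 * 9, self.c2), "b2": np.zeros(self.c2, DTYPE),
            "Wq": init(self.c2, self.da), "Wk": init(self.c2, self.da),
            "Wv": init(self.c2, self.c2), "Wo": init(self.c2, self.c2) * 0.1,
            "Wf": init(3 * self.c2, self.fdim), "bf": np.zeros(self.fdim, DTYPE),
            "T0": init(self.fdim, self.hidden),
            "T1": init(self.hidden, 2),
        }
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _zone_masks(self, h: int, w: int):
        """Three concentric radial zones over the feature-map positions.

        The vessel axis sits at the patch center, so pooling per radial zone
        keeps the "dark tube at some offset" signature that a global mean
        would wash out; it is also invariant to the arbitrary in-plane
        rotation of the patch frame."""
        if getattr(self, "_zones", None) is not None and self._zones[0] == (h, w):
            return self._zones[1]
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        r = np.sqrt((ii - (h - 1) / 2.0) ** 2 + (jj - (w - 1) / 2.0) ** 2).ravel()
        lim1, lim2 = h / 4.0, h / 2.0
        masks = [r < lim1, (r >= lim1) & (r < lim2), r >= lim2]
        self._zones = ((h, w), masks)
        return masks

    def _radial_pool(self, Xo: np.ndarray) -> np.ndarray:
        P = Xo.shape[1]
        side = int(round(np.sqrt(P)))
        masks = self._zone_masks(side, side)
        return np.concatenate([Xo[:, m, :].mean(axis=1) for m in masks], axis=1)

    # ---- forward ---------------------------------------------------------
    def _phi(self, x: np.ndarray, cache: dict | None = None):
        """Feature extractor: x (N, Cin*planes, 32, 32) -> Y (N, fdim)."""
        p = self.params
        cols1, (h1, w1) = im2col(x, 5, 2, 2)
        pre1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(pre1, 0.0)
        a1_img = a1.reshape(x.shape[0], h1, w1, self.c1).transpose(0, 3, 1, 2)
        cols2, (h2, w2) = im2col(a1_img, 3, 2, 1)
        pre2 = cols2 @ p["W2"] + p["b2"]
        X = np.maximum(pre2, 0.0)  # (N, P, c2) with P = h2*w2
        q = X @ p["Wq"]
        k = X @ p["Wk"]
        v = X @ p["Wv"]
        S = q @ k.transpose(0, 2, 1) / np.sqrt(self.da)
        A = softmax(S, axis=-1)
        Z = A @ v
        Xo = X + Z @ p["Wo"]
        y = self._radial_pool(Xo)
        Y = y @ p["Wf"] + p["bf"]
        if cache is not None:
            cache.update(
                x_shape=x.shape, cols1=cols1, pre1=pre1, a1_shape=a1_img.shape,
                cols2=cols2, pre2=pre2, X=X, q=q, k=k, v=v, A=A, Z=Z, Xo=Xo, y=y,
                hw1=(h1, w1), hw2=(h2, w2),
            )
        return Y

    def _gcn_w(self, nb_mask: np.ndarray) -> np.ndarray:
        """Normalized star adjacency D^-1/2 (A + I) D^-1/2 per sample."""
        b = nb_mask.shape[0]
        W = np.zeros((b, 1 + self.m, 1 + self.m), dtype=DTYPE)
        for i in range(b):
            A = np.eye(1 + self.m, dtype=DTYPE)
            for j in range(self.m):
                if nb_mask[i, j]:
                    A[0, 1 + j] = A[1 + j, 0] = 1.0
            d = A.sum(axis=1)
            dinv = 1.0 / np.sqrt(d)
            W[i] = A * dinv[:, None] * dinv[None, :]
        return W

    def forward(self, patches: np.ndarray, nb_mask: np.ndarray, cache: dict | None = None):
        """patches (B, 1+m, Cin*planes, 32, 32) -> class probabilities (B, 2).

        Column 0 of the class axis is the artery probability.
        """
        b, s = patches.shape[:2]
        flat = patches.reshape(b * s, *patches.shape[2:]).astype(DTYPE)
        Y = self._phi(flat, cache)
        H0 = Y.reshape(b, s, self.fdim)
        H0 = H0 * np.concatenate(
            [np.ones((b, 1)), nb_mask.astype(DTYPE)], axis=1
        )[:, :, None]
        W = self._gcn_w(nb_mask)
        M0 = W @ H0
        U1 = M0 @ self.params["T0"]
        H1 = np.maximum(U1, 0.0)
        M1 = W @ H1
        logits = (M1 @ self.params["T1"])[:, 0, :]
        if cache is not None:
            cache.update(H0=H0, W=W, M0=M0, U1=U1, H1=H1, M1=M1, nb_mask=nb_mask, b=b, s=s)
        return softmax(logits, axis=-1), logits

    # ---- backward --------------------------------------------------------
    def loss_and_grads(self, patches, nb_mask, targets):
        """Cross-entropy loss + gradients. targets: int array (B,), 0=artery."""
        p = self.params
        cache: dict = {}
        probs, logits = self.forward(patches, nb_mask, cache)
        b = cache["b"]
        loss = -float(np.mean(np.log(probs[np.arange(b), targets] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(b), targets] -= 1.0
        dlogits /= b

        g = {k: np.zeros_like(v) for k, v in p.items()}
        s = cache["s"]
        dM1 = np.zeros_like(cache["M1"])
        dM1[:, 0, :] = dlogits @ p["T1"].T
        g["T1"] = np.einsum("bsh,bsc->hc", cache["M1"], _center_only(dlogits, s))
        W = cache["W"]
        dH1 = W.transpose(0, 2, 1) @ dM1
        dU1 = dH1 * (cache["U1"] > 0)
        g["T0"] = np.einsum("bsf,bsh->fh", cache["M0"], dU1)
        dM0 = dU1 @ p["T0"].T
        dH0 = W.transpose(0, 2, 1) @ dM0
        mask_rows = np.concatenate(
            [np.ones((b, 1)), cache["nb_mask"].astype(DTYPE)], axis=1
        )[:, :, None]
        dH0 = dH0 * mask_rows
        dY = dH0.reshape(b * s, self.fdim)

        # phi backward
        dWf = cache["y"].T @ dY
        g["Wf"] = dWf
        g["bf"] = dY.sum(axis=0)
        dy = dY @ p["Wf"].T
        P = cache["Xo"].shape[1]
        side = int(round(np.sqrt(P)))
        masks = self._zone_masks(side, side)
        dXo = np.zeros_like(cache["Xo"])
        for zi, m in enumerate(masks):
            dz = dy[:, zi * self.c2:(zi + 1) * self.c2]
            dXo[:, m, :] += dz[:, None, :] / int(m.sum())
        g["Wo"] = np.einsum("npc,npd->cd", cache["Z"], dXo)
        dZ = dXo @ p["Wo"].T
        dX = dXo.copy()  # identity path
        A, v, q, k = cache["A"], cache["v"], cache["q"], cache["k"]
        dA = dZ @ v.transpose(0, 2, 1)
        dv = A.transpose(0, 2, 1) @ dZ
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.da)
        dq = dS @ k
        dk = dS.transpose(0, 2, 1) @ q
        X = cache["X"]
        g["Wq"] = np.einsum("npc,npd->cd", X, dq)
        g["Wk"] = np.einsum("npc,npd->cd", X, dk)
        g["Wv"] = np.einsum("npc,npd->cd", X, dv)
        dX += dq @ p["Wq"].T + dk @ p["Wk"].T + dv @ p["Wv"].T
        dpre2 = dX * (cache["pre2"] > 0)
        g["W2"] = np.einsum("npk,npc->kc", cache["cols2"], dpre2)
        g["b2"] = dpre2.sum(axis=(0, 1))
        dcols2 = dpre2 @ p["W2"].T
        da1 = col2im(dcols2, cache["a1_shape"], 3, 2, 1)
        h1, w1 = cache["hw1"]
        da1_cols = da1.transpose(0, 2, 3, 1).reshape(da1.shape[0], h1 * w1, self.c1)
        dpre1 = da1_cols * (cache["pre1"] > 0)
        g["W1"] = np.einsum("npk,npc->kc", cache["cols1"], dpre1)
        g["b1"] = dpre1.sum(axis=(0, 1))
        return loss, g, probs

    def sgd_step(self, grads, lr: float, momentum: float = 0.9):
        for k in self.params:
            self.velocity[k] = momentum * self.velocity[k] - lr * grads[k]
            self.params[k] += self.velocity[k]

    # ---- (de)serialization ----------------------------------------------
    def state_dict(self) -> dict:
        meta = dict(
            in_channels=self.in_channels, patch_planes=self.planes,
            conv_channels=(self.c1, self.c2), attention_dim=self.da,
            feature_dim=self.fdim, gcn_hidden=self.hidden, n_neighbors=self.m,
        )
        return {"meta": meta, "params": {k: v.copy() for k, v in self.params.items()}}

    @classmethod
    def from_state_dict(cls, state: dict) -> "NonLocalGCNClassifier":
        model = cls(**state["meta"])
        model.params = {k: np.asarray(v, DTYPE).copy() for k, v in state["params"].items()}
        model.velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
        return model


def _center_only(dlogits: np.ndarray, s: int) -> np.ndarray:
    b = dlogits.shape[0]
    out = np.zeros((b, s, dlogits.shape[1]), dtype=dlogits.dtype)
    out[:, 0, :] = dlogits
    return out
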