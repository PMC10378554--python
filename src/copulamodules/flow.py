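"""Rational-quadratic spline coupling flow on the unit square.

A copula density lives on [0,1]^2 with uniform margins, so the natural flow
design is a uniform base distribution on the square and a stack of coupling
layers, each of which transforms one coordinate by a monotone rational-
quadratic spline whose knots depend on the other (passive) coordinate.  The
model density follows from the change-of-variables formula; with a uniform
base it is simply the product of the spline derivatives, and maximum
likelihood amounts to maximizing the mean log |Jacobian|.

The conditioner is linear in a cosine feature basis of the passive
coordinate, phi_j(c) = cos(j*pi*c): this keeps the model expressive (the
spline parameters vary smoothly with the conditioning value) while making
back-propagation a single matrix product.  Gradients of the spline transform
and its log-derivative with respect to the local knot parameters are exact,
generated symbolically once per process and evaluated vectorized.

Training uses full-batch Adam.  Identical seeds give identical models on one
platform; bitwise identity across platforms is not promised.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["RQSFlow", "FlowConfig"]

_MIN_BIN = 1e-3  # minimum spline bin width/height
_MIN_DERIV = 1e-3  # minimum knot derivative


@lru_cache(maxsize=1)
def _spline_partials():
    """Symbolic partials of the RQ-spline transform and its log-derivative.

    Within bin k the monotone rational-quadratic segment is
        xi = (x - xk)/wk,  s = hk/wk,
        z  = yk + hk*(s*xi^2 + d0*xi*(1-xi)) / (s + (d0+d1-2s)*xi*(1-xi)),
        g' = s^2*(d1*xi^2 + 2s*xi*(1-xi) + d0*(1-xi)^2) / (...)^2.
    Returns a vectorized callable of (x, xk, wk, hk, d0, d1) yielding
    [z_off, log g', and the 12 partials of those two w.r.t. each argument].
    The additive yk enters z with derivative 1 and is handled by the caller.
    """
    import sympy as sp

    x, xk, wk, hk, d0, d1 = sp.symbols("x xk wk hk d0 d1")
    xi = (x - xk) / wk
    s = hk / wk
    q = xi * (1 - xi)
    den = s + (d0 + d1 - 2 * s) * q
    z_off = hk * (s * xi**2 + d0 * q) / den
    gp = s**2 * (d1 * xi**2 + 2 * s * q + d0 * (1 - xi) ** 2) / den**2
    ld = sp.log(gp)
    args = (x, xk, wk, hk, d0, d1)
    exprs = [z_off, ld]
    for e in (z_off, ld):
        exprs.extend(sp.diff(e, a) for a in args)
    return sp.lambdify(args, exprs, modules="numpy", cse=True)


def _softmax(x):
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    return float(np.log(np.expm1(y)))


class FlowConfig:
    """Hyperparameters of the spline coupling flow.

    n_layers coupling layers (alternating active coordinate), hidden_units
    cosine basis functions in the conditioner, n_knots spline bins.
    """

    def __init__(self, n_layers=2, hidden_units=32, n_knots=8,
                 train_fraction=0.9, max_epochs=300, learning_rate=0.05, seed=0):
        if min(n_layers, hidden_units, n_knots) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        self.n_layers = int(n_layers)
        self.hidden_units = int(hidden_units)
        self.n_knots = int(n_knots)
        self.train_fraction = float(train_fraction)
        self.max_epochs = int(max_epochs)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)

    def __repr__(self):
        return (f"FlowConfig(layers={self.n_layers}, hidden={self.hidden_units}, "
                f"knots={self.n_knots})")


class RQSFlow:
    """Spline coupling flow with a uniform base on [0,1]^2."""

    def __init__(self, n_layers=2, n_basis=32, n_knots=8, seed=0):
        self.n_layers = n_layers
        self.m = n_basis
        self.K = n_knots
        self.P = 3 * n_knots + 1  # K widths + K heights + (K+1) derivatives
        rng = np.random.default_rng(seed)
        self.W = []
        self.b = []
        b0 = np.zeros(self.P)
        b0[2 * self.K:] = _inv_softplus(1.0 - _MIN_DERIV)
        for _ in range(n_layers):
            self.W.append(rng.normal(0.0, 1e-3, size=(self.P, self.m)))
            self.b.append(b0.copy())

    # -- parameter plumbing -------------------------------------------------

    def _basis(self, c):
        j = np.arange(self.m)
        return np.cos(np.pi * j[None, :] * c[:, None])

    def _basis_deriv(self, c):
        j = np.arange(self.m)
        return -np.pi * j[None, :] * np.sin(np.pi * j[None, :] * c[:, None])

    def _layer_forward(self, layer, z, need_grad=False):
        """Transform the active coordinate of one layer; return cache."""
        K = self.K
        a = layer % 2
        p = 1 - a
        c = z[:, p]
        x = np.clip(z[:, a], 1e-9, 1.0 - 1e-9)
        phi = self._basis(c)
        raw = phi @ self.W[layer].T + self.b[layer][None, :]
        rw, rh, rd = raw[:, :K], raw[:, K:2 * K], raw[:, 2 * K:]
        sw = _softmax(rw)
        sh = _softmax(rh)
        alpha = 1.0 - K * _MIN_BIN
        w = _MIN_BIN + alpha * sw
        h = _MIN_BIN + alpha * sh
        kx = np.concatenate([np.zeros((len(x), 1)), np.cumsum(w, axis=1)], axis=1)
        ky = np.concatenate([np.zeros((len(x), 1)), np.cumsum(h, axis=1)], axis=1)
        kx[:, -1] = 1.0
        ky[:, -1] = 1.0
        d = _softplus(rd) + _MIN_DERIV
        k = np.sum(x[:, None] >= kx[:, 1:-1], axis=1)
        rows = np.arange(len(x))
        xk, wk = kx[rows, k], w[rows, k]
        yk, hk = ky[rows, k], h[rows, k]
        d0, d1 = d[rows, k], d[rows, k + 1]
        out = _spline_partials()(x, xk, wk, hk, d0, d1)
        z_off, ld = out[0], out[1]
        z_new = z.copy()
        z_new[:, a] = yk + z_off
        cache = None
        if need_grad:
            cache = dict(a=a, p=p, c=c, x=x, phi=phi, raw=raw, sw=sw, sh=sh,
                         alpha=alpha, k=k, partials=out, sig_d=1.0 / (1.0 + np.exp(-rd)))
        return z_new, ld, cache

    def log_density(self, uv):
        """Pointwise log copula density (base uniform contributes 0)."""
        uv = np.asarray(uv, dtype=float)
        z = np.clip(uv, 1e-9, 1.0 - 1e-9)
        total = np.zeros(len(z))
        for layer in range(self.n_layers):
            z, ld, _ = self._layer_forward(layer, z)
            total += ld
        return total

    def density(self, u, v):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return np.exp(self.log_density(np.column_stack([u, v])))

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, uv):
        n = len(uv)
        z = np.clip(uv, 1e-9, 1.0 - 1e-9)
        caches = []
        total_ld = np.zeros(n)
        for layer in range(self.n_layers):
            z, ld, cache = self._layer_forward(layer, z, need_grad=True)
            caches.append(cache)
            total_ld += ld
        loss = -float(np.mean(total_ld))
        lam = -1.0 / n  # d(loss)/d(per-sample logdet)
        gz = np.zeros((n, 2))
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        K = self.K
        for layer in reversed(range(self.n_layers)):
            cc = caches[layer]
            a, p, k = cc["a"], cc["p"], cc["k"]
            (_, _, dz_dx, dz_dxk, dz_dwk, dz_dhk, dz_dd0, dz_dd1,
             dl_dx, dl_dxk, dl_dwk, dl_dhk, dl_dd0, dl_dd1) = cc["partials"]
            go = gz[:, a]
            Gx = go * dz_dx + lam * dl_dx
            Gxk = go * dz_dxk + lam * dl_dxk
            Gwk = go * dz_dwk + lam * dl_dwk
            Gyk = go  # dz/dyk = 1, logdet free of yk
            Ghk = go * dz_dhk + lam * dl_dhk
            Gd0 = go * dz_dd0 + lam * dl_dd0
            Gd1 = go * dz_dd1 + lam * dl_dd1
            J = np.arange(K)[None, :]
            lt = J < k[:, None]
            eq = J == k[:, None]
            Gw_vec = Gxk[:, None] * lt + Gwk[:, None] * eq
            Gh_vec = Gyk[:, None] * lt + Ghk[:, None] * eq
            sw, sh, alpha = cc["sw"], cc["sh"], cc["alpha"]
            Rw = alpha * sw * (Gw_vec - np.sum(Gw_vec * sw, axis=1, keepdims=True))
            Rh = alpha * sh * (Gh_vec - np.sum(Gh_vec * sh, axis=1, keepdims=True))
            Jd = np.arange(K + 1)[None, :]
            Gd_vec = (Gd0[:, None] * (Jd == k[:, None])
                      + Gd1[:, None] * (Jd == k[:, None] + 1))
            Rd = Gd_vec * cc["sig_d"]
            R = np.concatenate([Rw, Rh, Rd], axis=1)
            phi = cc["phi"]
            gW[layer] = R.T @ phi
            gb[layer] = R.sum(axis=0)
            dphi = self._basis_deriv(cc["c"])
            g_c = np.sum(R * (dphi @ self.W[layer].T), axis=1)
            gz_prev = np.zeros_like(gz)
            gz_prev[:, a] = Gx
            gz_prev[:, p] = gz[:, p] + g_c
            gz = gz_prev
        return loss, gW, gb

    def fit(self, uv, max_epochs=300, learning_rate=0.02, val=None,
            check_every=10, verbose=False):
        """Full-batch Adam maximum likelihood.

        When a validation set ``val`` is given, the parameters achieving the
        best validation NLL (checked every ``check_every`` epochs) are kept
        — early stopping by snapshot, the overfitting control for flexible
        flows on limited data.  Without ``val`` the best training-loss
        parameters are kept.  Raises on persistent divergence after one
        retry at half the learning rate.
        """
        uv = np.asarray(uv, dtype=float)
        lr0 = learning_rate
        init_W = [w.copy() for w in self.W]
        init_b = [b.copy() for b in self.b]
        for attempt in range(2):
            try:
                return self._fit_once(uv, max_epochs, lr0 / (2**attempt),
                                      val, check_every, verbose)
            except FloatingPointError:
                # divergence: restore init and retry with halved learning rate
                self.W = [w.copy() for w in init_W]
                self.b = [b.copy() for b in init_b]
        raise RuntimeError("flow training diverged (non-finite loss) after retries")

    def _fit_once(self, uv, max_epochs, lr, val, check_every, verbose):
        beta1, beta2, aeps = 0.9, 0.999, 1e-8
        clip = 5.0  # global-norm gradient clip per layer
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        losses = []
        best = (np.inf, None, None)

        def monitor_loss(train_loss):
            if val is None:
                return train_loss
            return -float(np.mean(self.log_density(val)))

        for epoch in range(max_epochs):
            step_lr = lr * (0.5 if epoch > 2 * max_epochs // 3 else 1.0)
            loss, gW, gb = self._loss_and_grads(uv)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite loss")
            losses.append(loss)
            if epoch % check_every == 0:
                m = monitor_loss(loss)
                if m < best[0]:
                    best = (m, [w.copy() for w in self.W],
                            [b.copy() for b in self.b])
            t = epoch + 1
            corr = np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for i in range(self.n_layers):
                gnorm = np.sqrt(np.sum(gW[i] ** 2) + np.sum(gb[i] ** 2))
                scale = min(1.0, clip / max(gnorm, 1e-12))
                gWi, gbi = gW[i] * scale, gb[i] * scale
                mW[i] = beta1 * mW[i] + (1 - beta1) * gWi
                vW[i] = beta2 * vW[i] + (1 - beta2) * gWi**2
                self.W[i] -= step_lr * corr * mW[i] / (np.sqrt(vW[i]) + aeps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gbi
                vb[i] = beta2 * vb[i] + (1 - beta2) * gbi**2
                self.b[i] -= step_lr * corr * mb[i] / (np.sqrt(vb[i]) + aeps)
            if verbose and epoch % 50 == 0:
                print(f"epoch {epoch}: nll {loss:.4f}")
        final = monitor_loss(self._loss_and_grads(uv)[0])
        if best[0] < final and best[1] is not None:
            self.W, self.b = best[1], best[2]
        return np.asarray(losses)
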