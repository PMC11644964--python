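"""GRU and LSTM layers with backpropagation through time.

Both consume a ``(T, C)`` sequence and return the final hidden state
``(units,)``.  Gate equations follow the standard formulations:

GRU (update gate z, reset gate r; Cho convention)::

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    h~_t = act(x_t Wh + (r_t * h_{t-1}) Uh + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

LSTM (forget f, input i, output o gates, cell state c)::

    f_t = sigmoid(x_t Wf + h_{t-1} Uf + bf)
    i_t = sigmoid(x_t Wi + h_{t-1} Ui + bi)
    c~_t = act(x_t Wc + h_{t-1} Uc + bc)
    c_t = f_t * c_{t-1} + i_t * c~_t
    o_t = sigmoid(x_t Wo + h_{t-1} Uo + bo)
    h_t = o_t * act(c_t)

``act`` defaults to ReLU (the architectures here specify ReLU-activated
recurrent layers); tanh is available via ``activation="tanh"``.  Sigmoid
gate activations always lie in (0, 1) — asserted in the property tests.
Per-timestep gate values are cached on the layer after each forward pass
(``self.caches``) so the gate-range contract is introspectable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

from .layers import Layer, _ACTIVATIONS, glorot_uniform, orthogonal

__all__ = ["GRULayer", "LSTMLayer"]


class GRULayer(Layer):
    def __init__(self, in_dim: int, units: int, activation: str = "relu",
                 l2: float = 0.0) -> None:
        super().__init__()
        self.in_dim, self.units = int(in_dim), int(units)
        self.act, self.act_grad = _ACTIVATIONS[activation]
        self.activation = activation
        self.l2 = float(l2)
        self.stage = "gru"

    def init(self, rng):
        d, u = self.in_dim, self.units
        self.params = {}
        for g in ("z", "r", "h"):
            self.params[f"W{g}"] = glorot_uniform(rng, (d, u), d, u)
            self.params[f"U{g}"] = orthogonal(rng, u) * 0.5
            self.params[f"b{g}"] = np.zeros(u)
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        p = self.params
        h = np.zeros(self.units)
        self.caches = []
        for t in range(x.shape[0]):
            xt = x[t]
            z = sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            ah = xt @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"]
            h_cand = self.act(ah)
            h_new = (1.0 - z) * h + z * h_cand
            self.caches.append(
                {"x": xt, "h_prev": h, "z": z, "r": r, "ah": ah,
                 "h_cand": h_cand}
            )
            h = h_new
        self._T = x.shape[0]
        return h

    def backward(self, grad):
        p, g = self.params, self.grads
        dh = grad
        dx = np.zeros((self._T, self.in_dim))
        for t in range(self._T - 1, -1, -1):
            c = self.caches[t]
            z, r, h_prev = c["z"], c["r"], c["h_prev"]
            dz = dh * (c["h_cand"] - h_prev)
            dh_cand = dh * z
            dh_prev = dh * (1.0 - z)
            dah = dh_cand * self.act_grad(c["ah"])
            g["Wh"] += np.outer(c["x"], dah)
            g["Uh"] += np.outer(r * h_prev, dah)
            g["bh"] += dah
            drh = dah @ p["Uh"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            g["Wz"] += np.outer(c["x"], daz)
            g["Uz"] += np.outer(h_prev, daz)
            g["bz"] += daz
            g["Wr"] += np.outer(c["x"], dar)
            g["Ur"] += np.outer(h_prev, dar)
            g["br"] += dar
            dx[t] = daz @ p["Wz"].T + dar @ p["Wr"].T + dah @ p["Wh"].T
            dh = dh_prev + daz @ p["Uz"].T + dar @ p["Ur"].T
        return dx

    def l2_loss(self) -> float:
        if not self.l2:
            return 0.0
        return self.l2 * float(
            sum(np.sum(self.params[k] ** 2)
                for k in self.params if k.startswith(("W", "U")))
        )

    def add_l2_grads(self) -> None:
        if self.l2:
            for k in self.params:
                if k.startswith(("W", "U")):
                    self.grads[k] += 2.0 * self.l2 * self.params[k]


class LSTMLayer(Layer):
    def __init__(self, in_dim: int, units: int, activation: str = "relu",
                 l2: float = 0.0) -> None:
        super().__init__()
        self.in_dim, self.units = int(in_dim), int(units)
        self.act, self.act_grad = _ACTIVATIONS[activation]
        self.activation = activation
        self.l2 = float(l2)
        self.stage = "lstm"

    def init(self, rng):
        d, u = self.in_dim, self.units
        self.params = {}
        for gate in ("f", "i", "c", "o"):
            self.params[f"W{gate}"] = glorot_uniform(rng, (d, u), d, u)
            self.params[f"U{gate}"] = orthogonal(rng, u) * 0.5
            self.params[f"b{gate}"] = np.zeros(u)
        self.params["bf"] = np.ones(u)  # forget-gate bias at 1, the usual aid
        self.zero_grads()

    def forward(self, x, training=False, rng=None):
        p = self.params
        h = np.zeros(self.units)
        c_state = np.zeros(self.units)
        self.caches = []
        for t in range(x.shape[0]):
            xt = x[t]
            f = sigmoid(xt @ p["Wf"] + h @ p["Uf"] + p["bf"])
            i = sigmoid(xt @ p["Wi"] + h @ p["Ui"] + p["bi"])
            ac = xt @ p["Wc"] + h @ p["Uc"] + p["bc"]
            c_cand = self.act(ac)
            o = sigmoid(xt @ p["Wo"] + h @ p["Uo"] + p["bo"])
            c_new = f * c_state + i * c_cand
            h_new = o * self.act(c_new)
            self.caches.append(
                {"x": xt, "h_prev": h, "c_prev": c_state, "f": f, "i": i,
                 "o": o, "ac": ac, "c_cand": c_cand, "c": c_new}
            )
            h, c_state = h_new, c_new
        self._T = x.shape[0]
        return h

    def backward(self, grad):
        p, g = self.params, self.grads
        dh = grad
        dc = np.zeros(self.units)
        dx = np.zeros((self._T, self.in_dim))
        for t in range(self._T - 1, -1, -1):
            cc = self.caches[t]
            f, i, o = cc["f"], cc["i"], cc["o"]
            do = dh * self.act(cc["c"])
            dc = dc + dh * o * self.act_grad(cc["c"])
            df = dc * cc["c_prev"]
            di = dc * cc["c_cand"]
            dac = dc * i * self.act_grad(cc["ac"])
            daf = df * f * (1.0 - f)
            dai = di * i * (1.0 - i)
            dao = do * o * (1.0 - o)
            for name, da in (("f", daf), ("i", dai), ("c", dac), ("o", dao)):
                g[f"W{name}"] += np.outer(cc["x"], da)
                g[f"U{name}"] += np.outer(cc["h_prev"], da)
                g[f"b{name}"] += da
            dx[t] = (daf @ p["Wf"].T + dai @ p["Wi"].T + dac @ p["Wc"].T
                     + dao @ p["Wo"].T)
            dh = (daf @ p["Uf"].T + dai @ p["Ui"].T + dac @ p["Uc"].T
                  + dao @ p["Uo"].T)
            dc = dc * f
        return dx

    def l2_loss(self) -> float:
        if not self.l2:
            return 0.0
        return self.l2 * float(
            sum(np.sum(self.params[k] ** 2)
                for k in self.params if k.startswith(("W", "U")))
        )

    def add_l2_grads(self) -> None:
        if self.l2:
            for k in self.params:
                if k.startswith(("W", "U")):
                    self.grads[k] += 2.0 * self.l2 * self.params[k]
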