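"""Compiled fast path for lifetime simulation.

Evaluating one association set means 90 episodes x 4 associations x 2
phases x 5 synchronous steps = 3600 network updates, and fitness/GLA
measurements repeat this hundreds to thousands of times.  The inner loop is
therefore compiled with numba.  The kernel reproduces exactly the semantics
of :class:`evoplast.network.PlasticNetwork` (same update order, same
clamping); the pure-Python path is kept as the reference implementation and
the two are cross-checked in the test suite.

All randomness is consumed from pre-drawn uniform arrays so that the fast
and reference paths see identical random streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# Input-vector layouts (must match task.encode_input_vector):
#   style 0 (10 lines): [0..3] stimulus | 4 reward+ | 5 reward- | [6..9] feedback
#   style 1 (9 lines):  [0..3] stimulus | 4 signed reward | [5..8] feedback
REWARD_TWO_LINES = 0
REWARD_SIGNED_LINE = 1


@dataclass
class CompiledNetwork:
    """Flat-array view of a PlasticNetwork for the kernel."""

    n: int
    esrc: np.ndarray
    etgt: np.ndarray
    esgn: np.ndarray
    emag: np.ndarray
    estd: np.ndarray        # uint8: source is standard
    eplastic: np.ndarray    # int64 indices of plastic edges
    bias: np.ndarray
    input_idx: np.ndarray
    output_idx: np.ndarray
    lam: float
    eta: float
    w_min: float
    w_max: float

    @classmethod
    def from_network(cls, net) -> "CompiledNetwork":
        return cls(
            n=net.n_neurons,
            esrc=net._esrc.copy(),
            etgt=net._etgt.copy(),
            esgn=net._esgn.copy(),
            emag=net._emag.copy(),
            estd=net._estd.astype(np.uint8),
            eplastic=np.flatnonzero(net._eplastic).astype(np.int64),
            bias=net._bias.copy(),
            input_idx=net._input_idx.copy(),
            output_idx=net._output_idx.copy(),
            lam=net.params.lam,
            eta=net.params.eta,
            w_min=net.params.w_min,
            w_max=net.params.w_max,
        )

    @property
    def n_plastic(self) -> int:
        return int(self.eplastic.size)


@njit(cache=True)
def _lifetime(
    esrc,
    etgt,
    esgn,
    emag0,
    estd,
    eplastic,
    bias,
    input_idx,
    output_idx,
    lam,
    eta,
    w_min,
    w_max,
    assoc,
    n_episodes,
    n_steps,
    tau,
    reward_mag,
    reward_style,
    reset_u,
    softmax_u,
):  # pragma: no cover - compiled
    n = bias.shape[0]
    n_edges = esrc.shape[0]
    n_in = input_idx.shape[0]
    n_out = output_idx.shape[0]
    n_assoc = assoc.shape[0]

    w = emag0.copy()
    for k in range(eplastic.shape[0]):
        w[eplastic[k]] = w_min + reset_u[k] * (w_max - w_min)

    o = np.zeros(n)
    x = np.zeros(n_in)
    net = np.zeros(n)
    m = np.zeros(n)
    outs = np.zeros(n_out)
    p = np.zeros(n_out)
    success = np.zeros(n_assoc, np.int8)
    raw = np.zeros((n_assoc, n_out))
    up = 0

    for ep in range(n_episodes):
        for s in range(n_assoc):
            for phase in range(2):
                if phase == 0:
                    for i in range(n_in):
                        x[i] = 0.0
                    x[s] = 1.0
                    action = -1
                else:
                    # softmax selection on the phase-A outputs
                    for i in range(n_out):
                        outs[i] = o[output_idx[i]]
                    mx = outs[0]
                    for i in range(1, n_out):
                        if outs[i] > mx:
                            mx = outs[i]
                    tot = 0.0
                    for i in range(n_out):
                        p[i] = np.exp((outs[i] - mx) / tau)
                        tot += p[i]
                    u = softmax_u[up] * tot
                    up += 1
                    action = n_out - 1
                    acc = 0.0
                    for i in range(n_out):
                        acc += p[i]
                        if u < acc:
                            action = i
                            break
                    correct = action == assoc[s]
                    if reward_style == 0:
                        if correct:
                            x[4] = reward_mag
                        else:
                            x[5] = reward_mag
                        x[6 + action] = 1.0
                    else:
                        if correct:
                            x[4] = reward_mag
                        else:
                            x[4] = -reward_mag
                        x[5 + action] = 1.0
                    if ep == n_episodes - 1:
                        if correct:
                            success[s] = 1
                        for i in range(n_out):
                            raw[s, i] = outs[i]
                for t in range(n_steps):
                    # clamp inputs, then synchronous update
                    for i in range(n_in):
                        o[input_idx[i]] = x[i]
                    for i in range(n):
                        net[i] = bias[i]
                        m[i] = 0.0
                    for e in range(n_edges):
                        c = esgn[e] * w[e] * o[esrc[e]]
                        if estd[e] == 1:
                            net[etgt[e]] += c
                        else:
                            m[etgt[e]] += c
                    for i in range(n):
                        o[i] = 1.0 / (1.0 + np.exp(-lam * net[i]))
                    for i in range(n_in):
                        o[input_idx[i]] = x[i]
                    # modulated Hebbian update on plastic edges
                    for k in range(eplastic.shape[0]):
                        e = eplastic[k]
                        nw = w[e] + eta * np.tanh(m[etgt[e]]) * o[etgt[e]] * o[esrc[e]]
                        if nw < w_min:
                            nw = w_min
                        elif nw > w_max:
                            nw = w_max
                        w[e] = nw
    return success, raw


def run_lifetime(
    cnet: CompiledNetwork,
    assoc: np.ndarray,
    n_episodes: int,
    n_steps: int,
    tau: float,
    reward_mag: float,
    reward_style: int,
    reset_u: np.ndarray,
    softmax_u: np.ndarray,
):
    """Simulate one lifetime on one association set.

    Returns ``(success, raw)``: per-association correctness on the last
    episode (int8 array) and the pre-softmax output vectors recorded there.
    """
    return _lifetime(
        cnet.esrc,
        cnet.etgt,
        cnet.esgn,
        cnet.emag,
        cnet.estd,
        cnet.eplastic,
        cnet.bias,
        cnet.input_idx,
        cnet.output_idx,
        cnet.lam,
        cnet.eta,
        cnet.w_min,
        cnet.w_max,
        np.asarray(assoc, dtype=np.int64),
        n_episodes,
        n_steps,
        tau,
        reward_mag,
        reward_style,
        np.asarray(reset_u, dtype=float),
        np.asarray(softmax_u, dtype=float),
    )
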