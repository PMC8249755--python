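"""Assembly of batched simulation arrays from named log-scaling parameters.

Every tunable quantity of the neural-mass model is a log-scaling of a
shipped default magnitude, so an effective array entry is
``base * exp(sum of the log-scalings that touch it)``. A ``SimTemplate``
precomputes, for a given network architecture and condition, the sparse
coupling pattern, the base magnitudes, and indicator matrices mapping the
full named parameter vector onto array entries; ``materialize`` then turns
a (B, P) matrix of parameter vectors into batched kernel inputs with a
handful of matrix exponentials.
"""

from __future__ import annotations

import numpy as np

POPULATIONS = ("ss", "sp", "ii", "dp")

#: intrinsic excitatory connections (AMPA + NMDA mediated)
EXC_CONNS = (("ss", "sp"), ("ss", "ii"), ("sp", "dp"), ("dp", "ii"))
#: intrinsic inhibitory connections (GABA mediated), self-gains included
INH_CONNS = (("ii", "ss"), ("ii", "sp"), ("ii", "dp"),
             ("ss", "ss"), ("sp", "sp"), ("ii", "ii"), ("dp", "dp"))


def conn_name(a: str, b: str) -> str:
    return f"self_{a}" if a == b else f"{a}_to_{b}"


def pop_index(spec, region: str, pop: str) -> int:
    return 4 * spec.region_index(region) + POPULATIONS.index(pop)


def param_names(spec) -> list[str]:
    """Canonical ordering of the full named parameter vector for ``spec``."""
    names = []
    for ch in ("ampa", "gaba", "nmda"):
        for r in spec.regions:
            names.append(f"kappa_{ch}:{r}")
    for r in spec.regions:
        for a, b in EXC_CONNS + INH_CONNS:
            names.append(f"G:{r}:{conn_name(a, b)}")
    for ch in ("ampa", "nmda"):
        for src, dst in spec.edges:
            names.append(f"A_{ch}:{src}->{dst}")
    for src, dst in spec.edges:
        names.append(f"B:{src}->{dst}")
    names += ["input_onset", "input_width", "input_amp"]
    for r in spec.regions:
        names.append(f"obs_gain:{r}")
    return names


class SimTemplate:
    """Precomputed structure for one (constants, magnitudes, spec, condition)."""

    def __init__(self, params, spec, condition: str):
        if condition not in ("angry", "happy"):
            raise ValueError(f"unknown condition {condition!r}")
        self.spec = spec
        self.condition = condition
        self.names = param_names(spec)
        self.index = {n: i for i, n in enumerate(self.names)}
        P = len(self.names)
        mag = params.magnitudes
        k = params.constants

        entA, entG, entN = [], [], []  # (row, col, base_w, touching names)
        for r in spec.regions:
            for a, b in EXC_CONNS:
                cn = conn_name(a, b)
                gname = f"G:{r}:{cn}"
                row, col = pop_index(spec, r, b), pop_index(spec, r, a)
                ratio = mag.get(f"nmda_ratio_{cn}_{r}",
                                mag.get(f"nmda_ratio_{cn}", mag["nmda_ratio"]))
                ge = mag.get(f"g_exc_{cn}_{r}", mag[f"g_exc_{cn}"])
                entA.append((row, col, ge, [gname]))
                entN.append((row, col, ge * ratio, [gname]))
            for a, b in INH_CONNS:
                cn = conn_name(a, b)
                gname = f"G:{r}:{cn}"
                row, col = pop_index(spec, r, b), pop_index(spec, r, a)
                gi = mag.get(f"g_inh_{cn}_{r}", mag[f"g_inh_{cn}"])
                entG.append((row, col, gi, [gname]))
        happy = condition == "happy"

        def emag(kind, src, dst):
            # per-edge default override, else the global magnitude
            return mag.get(f"{kind}_{src}->{dst}", mag[kind])

        for src, dst in spec.forward_edges:
            bnames = [f"B:{src}->{dst}"] if happy else []
            col = pop_index(spec, src, "sp")
            row = pop_index(spec, dst, "ss")
            entA.append((row, col, emag("ext_fwd_ampa", src, dst),
                         [f"A_ampa:{src}->{dst}"] + bnames))
            entN.append((row, col, emag("ext_fwd_nmda", src, dst),
                         [f"A_nmda:{src}->{dst}"] + bnames))
        for src, dst in spec.backward_edges:
            bnames = [f"B:{src}->{dst}"] if happy else []
            col = pop_index(spec, src, "dp")
            for tgt in ("sp", "ii"):
                row = pop_index(spec, dst, tgt)
                entA.append((row, col, emag("ext_bwd_ampa", src, dst),
                             [f"A_ampa:{src}->{dst}"] + bnames))
                entN.append((row, col, emag("ext_bwd_nmda", src, dst),
                             [f"A_nmda:{src}->{dst}"] + bnames))

        def build(entries):
            rows = np.array([e[0] for e in entries], dtype=np.int64)
            cols = np.array([e[1] for e in entries], dtype=np.int64)
            w0 = np.array([e[2] for e in entries], dtype=float)
            M = np.zeros((P, len(entries)))
            for j, e in enumerate(entries):
                for n in e[3]:
                    M[self.index[n], j] = 1.0
            return rows, cols, w0, M

        self.rowsA, self.colsA, self.wA0, self.MA = build(entA)
        self.rowsG, self.colsG, self.wG0, self.MG = build(entG)
        self.rowsN, self.colsN, self.wN0, self.MN = build(entN)

        kap0 = {"ampa": 1.0 / k["tau_ampa"], "gaba": 1.0 / k["tau_gaba"],
                "nmda": 1.0 / k["tau_nmda"]}
        self.kap0 = {ch: np.full(16, kap0[ch]) for ch in kap0}
        self.Mkap = {}
        for ch in kap0:
            M = np.zeros((P, 16))
            for r in spec.regions:
                i0 = 4 * spec.region_index(r)
                M[self.index[f"kappa_{ch}:{r}"], i0:i0 + 4] = 1.0
            self.Mkap[ch] = M

        self.cmask = np.zeros(16)
        self.cmask[pop_index(spec, spec.input_region, "ss")] = 1.0
        self.onset0 = mag["input_onset"]
        self.width0 = mag["input_width"]
        self.amp0 = mag["input_amp"]
        self.i_onset = self.index["input_onset"]
        self.i_width = self.index["input_width"]
        self.i_amp = self.index["input_amp"]

        self.obs0 = np.full(len(spec.regions), mag["obs_gain"])
        self.Mobs = np.zeros((P, len(spec.regions)))
        for r in spec.regions:
            self.Mobs[self.index[f"obs_gain:{r}"], spec.region_index(r)] = 1.0

        self.jw = np.asarray(params.j_weights, dtype=float)
        self.consts = (k["V_L"], k["V_E"], k["V_I"], k["V_thr"], k["s"],
                       k["a_mg"], k["g_L"], k["Cm"])

    def materialize(self, values: np.ndarray) -> dict:
        """Batched kernel arrays for a (B, P) matrix of named log-scalings."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        if v.shape[1] != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} parameters, got {v.shape[1]}")

        def ex(z):
            # clip so extreme optimizer proposals stay finite
            return np.exp(np.clip(z, -30.0, 30.0))

        out = {
            "wA": self.wA0 * ex(v @ self.MA),
            "wG": self.wG0 * ex(v @ self.MG),
            "wN": self.wN0 * ex(v @ self.MN),
            "kapA": self.kap0["ampa"] * ex(v @ self.Mkap["ampa"]),
            "kapG": self.kap0["gaba"] * ex(v @ self.Mkap["gaba"]),
            "kapN": self.kap0["nmda"] * ex(v @ self.Mkap["nmda"]),
            "onset": self.onset0 * ex(v[:, self.i_onset]),
            "width": self.width0 * ex(v[:, self.i_width]),
            "amp": self.amp0 * ex(v[:, self.i_amp]),
            "obsg": self.obs0 * ex(v @ self.Mobs),
        }
        return out

    def values_matrix(self, params, B: int = 1) -> np.ndarray:
        """Full (B, P) values matrix replicating ``params.values``."""
        v = np.zeros(len(self.names))
        for n, x in params.values.items():
            v[self.index[n]] = x
        return np.tile(v, (B, 1))
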