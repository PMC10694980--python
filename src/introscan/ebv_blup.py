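"""Pedigree BLUP for repeated litter-size records.

Implements the tabular numerator relationship matrix A, its direct sparse
inverse (Henderson's rules with inbreeding-aware diagonal weights), and the
mixed-model equations for the repeated-records animal model

    y = Xb + Z_u u + Z_m m + Z_p p + e

with fixed parity and year-season effects, an A-structured additive sow
effect u, an A-structured mating-boar effect m, an identity-structured
permanent-environment effect p, and i.i.d. residuals.  Additive solutions
are the estimated breeding values (EBVs) for every pedigree member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "Pedigree",
    "VarianceComponents",
    "MMESolution",
    "numerator_relationship_matrix",
    "a_inverse",
    "solve_mme",
]

UNKNOWN = "0"


class PedigreeCycleError(ValueError):
    pass


class Pedigree:
    """Ordered pedigree records; parents always precede offspring internally."""

    def __init__(self, frame: pd.DataFrame):
        df = frame[["id", "sire", "dam"]].astype(str).copy()
        df = df.replace({"sire": {"NA": UNKNOWN, "nan": UNKNOWN, "": UNKNOWN},
                         "dam": {"NA": UNKNOWN, "nan": UNKNOWN, "": UNKNOWN}})
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate pedigree id {dup!r}")
        known = set(df["id"])
        # parents mentioned but not listed become founders
        phantoms = sorted(
            {p for p in pd.concat([df["sire"], df["dam"]]) if p != UNKNOWN} - known
        )
        if phantoms:
            df = pd.concat(
                [pd.DataFrame({"id": phantoms, "sire": UNKNOWN, "dam": UNKNOWN}), df],
                ignore_index=True,
            )
        self._order(df)

    def _order(self, df: pd.DataFrame) -> None:
        idx = {iid: k for k, iid in enumerate(df["id"])}
        sires = df["sire"].tolist()
        dams = df["dam"].tolist()
        ids = df["id"].tolist()
        n = len(ids)
        state = [0] * n  # 0 unseen, 1 visiting, 2 done
        order: list[int] = []

        def visit(k: int, stack: list[str]) -> None:
            if state[k] == 2:
                return
            if state[k] == 1:
                cycle = stack[stack.index(ids[k]):] + [ids[k]]
                raise PedigreeCycleError(
                    "pedigree cycle: " + " -> ".join(cycle)
                )
            state[k] = 1
            stack.append(ids[k])
            for p in (sires[k], dams[k]):
                if p != UNKNOWN:
                    visit(idx[p], stack)
            stack.pop()
            state[k] = 2
            order.append(k)

        import sys
        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10 * n + 1000))
        try:
            for k in range(n):
                visit(k, [])
        finally:
            sys.setrecursionlimit(limit)

        self.ids: list[str] = [ids[k] for k in order]
        self._pos = {iid: k for k, iid in enumerate(self.ids)}
        self.sire_idx = np.array(
            [self._pos.get(sires[k], -1) if sires[k] != UNKNOWN else -1
             for k in order], dtype=np.int64)
        self.dam_idx = np.array(
            [self._pos.get(dams[k], -1) if dams[k] != UNKNOWN else -1
             for k in order], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        return self._pos[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._pos

    def extended_with(self, extra_ids: list[str]) -> "Pedigree":
        """Return a pedigree with phantom founders appended for unseen ids."""
        new = [i for i in extra_ids if i not in self]
        if not new:
            return self
        df = self.to_frame()
        add = pd.DataFrame({"id": new, "sire": UNKNOWN, "dam": UNKNOWN})
        return Pedigree(pd.concat([df, add], ignore_index=True))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire_idx],
            "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam_idx],
        })

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:3]) != ["id", "sire", "dam"]:
            df.columns = ["id", "sire", "dam"] + list(df.columns[3:])
        return cls(df)


@dataclass
class VarianceComponents:
    sigma_u2: float = 1.0
    sigma_m2: float = 0.3
    sigma_p2: float = 0.5
    sigma_e2: float = 8.0

    def __post_init__(self) -> None:
        if min(self.sigma_u2, self.sigma_m2, self.sigma_p2) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma_e2 <= 0:
            raise ValueError("residual variance must be positive")


def numerator_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Wright's A by the tabular method (pedigree-ordered, dense)."""
    n = len(ped)
    a = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for j in range(n):
        sj, dj = s[j], d[j]
        a[j, j] = 1.0 + (0.5 * a[sj, dj] if sj >= 0 and dj >= 0 else 0.0)
        row = np.zeros(j)
        if sj >= 0:
            row += 0.5 * a[sj, :j]
        if dj >= 0:
            row += 0.5 * a[dj, :j]
        a[j, :j] = row
        a[:j, j] = row
    return a


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding-adjusted weights.

    The Mendelian-sampling variance d_j uses parental inbreeding
    coefficients obtained from the tabular A diagonal.
    """
    n = len(ped)
    f = np.diag(numerator_relationship_matrix(ped)) - 1.0  # inbreeding coeffs
    s, d = ped.sire_idx, ped.dam_idx
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for j in range(n):
        sj, dj = s[j], d[j]
        dj_var = 1.0
        if sj >= 0:
            dj_var -= 0.25 * (1.0 + f[sj])
        if dj >= 0:
            dj_var -= 0.25 * (1.0 + f[dj])
        w = 1.0 / dj_var
        add(j, j, w)
        for p in (sj, dj):
            if p >= 0:
                add(p, j, -0.5 * w)
                add(j, p, -0.5 * w)
                for q in (sj, dj):
                    if q >= 0:
                        add(p, q, 0.25 * w)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


@dataclass
class MMESolution:
    fixed: pd.Series          # labeled fixed-effect solutions
    ebv: pd.Series            # additive solutions for every pedigree member
    boar: pd.Series | None    # mating-boar solutions (pedigree-indexed)
    pe: pd.Series | None      # permanent-environment solutions (sows with records)


def _dummy(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies, first (sorted) level dropped as reference."""
    levels = sorted(values.astype(str).unique())
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((values.astype(str) == lev).to_numpy(float))
        names.append(f"{prefix}[{lev}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), names


def solve_mme(
    phen: pd.DataFrame,
    ped: Pedigree,
    vc: VarianceComponents,
) -> MMESolution:
    """Solve Henderson's mixed-model equations for the repeated-records model.

    ``phen`` needs columns ``sow parity yearseason boar tnb``.  Sows and
    boars absent from the pedigree are added as phantom founders.  Zero
    variance components drop the corresponding random block with a warning.
    Returns labeled solutions; EBVs cover all pedigree members, including
    phenotype-less ancestors (who receive parent-average style solutions).
    """
    required = {"sow", "parity", "yearseason", "boar", "tnb"}
    if not required <= set(phen.columns):
        raise ValueError(f"phenotype table missing columns {required - set(phen.columns)}")
    phen = phen.reset_index(drop=True)
    ped = ped.extended_with(
        list(phen["sow"].astype(str)) + list(phen["boar"].astype(str))
    )
    n_rec = len(phen)
    n_ped = len(ped)
    y = phen["tnb"].to_numpy(float)

    # fixed effects: intercept + parity + year-season (first levels dropped)
    xp, names_p = _dummy(phen["parity"], "parity")
    xy, names_y = _dummy(phen["yearseason"], "yearseason")
    x = np.column_stack([np.ones(n_rec), xp, xy])
    x_names = ["intercept"] + names_p + names_y
    xs = sparse.csr_matrix(x)

    sow_idx = np.array([ped.index_of(s) for s in phen["sow"].astype(str)])
    boar_idx = np.array([ped.index_of(b) for b in phen["boar"].astype(str)])
    ones = np.ones(n_rec)
    zu = sparse.csr_matrix((ones, (np.arange(n_rec), sow_idx)), shape=(n_rec, n_ped))

    blocks = [("fixed", xs, None)]
    use_u = vc.sigma_u2 > 0
    use_m = vc.sigma_m2 > 0
    use_p = vc.sigma_p2 > 0
    if not use_u:
        warnings.warn("sigma_u2 = 0: additive block dropped; EBVs are all zero")
    if not use_m:
        warnings.warn("sigma_m2 = 0: mating-boar block dropped")
    if not use_p:
        warnings.warn("sigma_p2 = 0: permanent-environment block dropped")

    ainv = a_inverse(ped) if (use_u or use_m) else None
    zm = sparse.csr_matrix((ones, (np.arange(n_rec), boar_idx)), shape=(n_rec, n_ped))
    sows = sorted(set(phen["sow"].astype(str)))
    sow_pos = {s: k for k, s in enumerate(sows)}
    pe_idx = np.array([sow_pos[s] for s in phen["sow"].astype(str)])
    zp = sparse.csr_matrix((ones, (np.arange(n_rec), pe_idx)),
                           shape=(n_rec, len(sows)))

    if use_u:
        blocks.append(("u", zu, ainv * (vc.sigma_e2 / vc.sigma_u2)))
    if use_m:
        blocks.append(("m", zm, ainv * (vc.sigma_e2 / vc.sigma_m2)))
    if use_p:
        blocks.append(("p", zp, sparse.identity(len(sows), format="csr")
                       * (vc.sigma_e2 / vc.sigma_p2)))

    mats = [b[1] for b in blocks]
    lhs_rows = []
    for i, zi in enumerate(mats):
        row = [zi.T @ zj for zj in mats]
        if blocks[i][2] is not None:
            row[i] = row[i] + blocks[i][2]
        lhs_rows.append(row)
    lhs = sparse.bmat(lhs_rows, format="csc")
    rhs = np.concatenate([np.asarray((zi.T @ y)).ravel() for zi in mats])

    try:
        sol = spsolve(lhs, rhs)
    except Exception as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"MME solve failed: {exc}") from exc
    if np.isnan(sol).any():
        raise np.linalg.LinAlgError(
            "singular mixed-model equations (check fixed-effect constraints)"
        )

    off = 0
    parts: dict[str, np.ndarray] = {}
    for (name, zi, _), width in zip(blocks, [m.shape[1] for m in mats]):
        parts[name] = sol[off:off + width]
        off += width

    fixed = pd.Series(parts["fixed"], index=x_names, name="estimate")
    if use_u:
        ebv = pd.Series(parts["u"], index=ped.ids, name="ebv")
    else:
        ebv = pd.Series(0.0, index=ped.ids, name="ebv")
    boar = pd.Series(parts["m"], index=ped.ids, name="boar") if use_m else None
    pe = pd.Series(parts["p"], index=sows, name="pe") if use_p else None
    return MMESolution(fixed=fixed, ebv=ebv, boar=boar, pe=pe)
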