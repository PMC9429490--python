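"""Independent ML covariance-structure fitter used only as a test oracle.

Deliberately written without importing the package's engine: different
identification (first loading per latent fixed to 1, latent residual
variances free, versus the package's unit-variance convention), a different
optimizer (BFGS with numeric gradients), and its own covariance algebra.
Standardized solutions from the two routes must agree, which is the basis of
the cross-implementation equivalence tests.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


class OracleModel:
    """A small latent model: blocks of indicators, directed paths, exo covs.

    blocks: list of indicator counts per latent (latent j owns a contiguous
    block of rows).  edges: list of (source, target) latent index pairs.
    exo_covs: list of (a, b) latent index pairs with a free covariance.
    """

    def __init__(self, blocks, edges, exo_covs=()):
        self.blocks = list(blocks)
        self.edges = list(edges)
        self.exo_covs = list(exo_covs)
        self.m = len(blocks)
        self.p = sum(blocks)
        targets = {t for _, t in edges}
        self.endo = [j for j in range(self.m) if j in targets]
        # free loadings: all but the first indicator of each block
        self.free_load = []
        row = 0
        self.first_rows = []
        self.block_of_row = []
        for j, k in enumerate(self.blocks):
            self.first_rows.append(row)
            for r in range(row, row + k):
                self.block_of_row.append(j)
                if r != row:
                    self.free_load.append((r, j))
            row += k

    @property
    def n_params(self):
        return (
            len(self.free_load)
            + len(self.edges)
            + len(self.exo_covs)
            + self.m  # latent (residual) variances, all free in this convention
            + self.p  # error variances
        )

    def matrices(self, x):
        lam = np.zeros((self.p, self.m))
        for r, j in zip(self.first_rows, range(self.m)):
            lam[r, j] = 1.0
        k = 0
        for r, j in self.free_load:
            lam[r, j] = x[k]
            k += 1
        b = np.zeros((self.m, self.m))
        for s, t in self.edges:
            b[t, s] = x[k]
            k += 1
        psi = np.zeros((self.m, self.m))
        for a, c in self.exo_covs:
            psi[a, c] = psi[c, a] = x[k]
            k += 1
        for j in range(self.m):
            psi[j, j] = x[k]
            k += 1
        theta = np.diag(x[k : k + self.p])
        return lam, b, psi, theta

    def implied(self, x):
        lam, b, psi, theta = self.matrices(x)
        a = np.linalg.inv(np.eye(self.m) - b)
        return lam @ a @ psi @ a.T @ lam.T + theta

    def fml(self, x, s_mat, logdet_s):
        sigma = self.implied(x)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        return logdet + float(np.trace(np.linalg.solve(sigma, s_mat))) - logdet_s - self.p

    def fit(self, s_mat, n):
        sign, logdet_s = np.linalg.slogdet(s_mat)
        assert sign > 0
        x0 = np.concatenate(
            [
                np.ones(len(self.free_load)),
                np.zeros(len(self.edges)),
                np.zeros(len(self.exo_covs)),
                0.5 * np.ones(self.m),
                0.5 * np.diag(s_mat),
            ]
        )
        res = minimize(
            self.fml,
            x0,
            args=(s_mat, logdet_s),
            method="BFGS",
            options={"maxiter": 5000, "gtol": 1e-10},
        )
        return res

    def standardized(self, x):
        """Standardized loadings (per row) and paths (per edge)."""
        lam, b, psi, theta = self.matrices(x)
        a = np.linalg.inv(np.eye(self.m) - b)
        sig_l = a @ psi @ a.T
        sigma = lam @ sig_l @ lam.T + theta
        d_l = np.sqrt(np.diag(sig_l))
        d_o = np.sqrt(np.diag(sigma))
        load_std = np.array(
            [lam[r, self.block_of_row[r]] * d_l[self.block_of_row[r]] / d_o[r] for r in range(self.p)]
        )
        path_std = np.array([b[t, s] * d_l[s] / d_l[t] for s, t in self.edges])
        return load_std, path_std
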