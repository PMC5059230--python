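"""Great-circle distances and the Mantel isolation-by-distance test.

Geographic distance is the haversine great-circle distance on a sphere of
radius 6371 km.  Accessions without coordinates are excluded before the
distance matrices are formed.  The Mantel statistic is the Pearson
correlation of the lower triangles of the genetic and geographic distance
matrices; its null distribution comes from jointly permuting the rows and
columns of one matrix, with the standard +1 correction so the p-value is
never zero.  The test is two-sided on |r| by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen_stats import PairwiseMatrix

logger = logging.getLogger("orscpop")

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    r2: float
    p: float
    n_perm: int
    n: int


def geo_distance(a, b) -> float:
    """Haversine distance in km between (lat, lon) points in decimal degrees.

    Returns NaN if either coordinate is missing.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    if any(pd.isna(v) for v in (lat1, lon1, lat2, lon2)):
        return np.nan
    if not (-90 <= lat1 <= 90 and -90 <= lat2 <= 90):
        raise ValueError("latitude out of [-90, 90]")
    if not (-180 <= lon1 <= 180 and -180 <= lon2 <= 180):
        raise ValueError("longitude out of [-180, 180]")
    phi1, phi2, dphi, dlmb = np.radians([lat1, lat2, lat2 - lat1, lon2 - lon1])
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_matrix(meta: pd.DataFrame, log_km: bool = False) -> PairwiseMatrix:
    """Pairwise great-circle km between accessions with known coordinates.

    Accessions with missing latitude or longitude are dropped (logged),
    mirroring the exclusion of collection sites with unknown location.
    With ``log_km`` distances are log(1 + km).
    """
    ok = meta["latitude"].notna() & meta["longitude"].notna()
    if (~ok).any():
        logger.info("geographic_matrix: excluded %d accession(s) without coordinates",
                    int((~ok).sum()))
    sub = meta[ok]
    ids = list(sub["accession_id"])
    lat = np.radians(sub["latitude"].to_numpy(dtype=float))
    lon = np.radians(sub["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    if log_km:
        d = np.log1p(d)
    return PairwiseMatrix(labels=ids, values=d)


def mantel(
    genetic: PairwiseMatrix,
    geographic: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    Both matrices must carry the same labels in the same order, n >= 4.
    r is the Pearson correlation of lower-triangle entries; the p-value is
    (#{permuted statistic >= observed} + 1) / (n_perm + 1), comparing |r|
    for the two-sided test and signed r for ``alternative='greater'``.
    With ``exact`` (n <= 8) all n! label permutations are enumerated and
    the p-value is the exact fraction, without the +1 correction.
    """
    if list(genetic.labels) != list(geographic.labels):
        raise ValueError("matrices must share labels in the same order")
    n = len(genetic.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 accessions")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    A, B = genetic.values, geographic.values
    il = np.tril_indices(n, k=-1)
    x = A[il]
    y0 = B[il]
    if (x.std() <= 1e-9 * (1 + np.abs(x).max())
            or y0.std() <= 1e-9 * (1 + np.abs(y0).max())):
        raise ValueError("degenerate matrix: zero variance in lower triangle")
    xc = x - x.mean()
    x_norm = np.sqrt(xc @ xc)

    def corr(mat_b: np.ndarray) -> float:
        y = mat_b[il]
        yc = y - y.mean()
        return float((xc @ yc) / (x_norm * np.sqrt(yc @ yc)))

    r_obs = corr(B)
    if exact:
        import itertools
        import math

        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        count = 0
        for perm in itertools.permutations(range(n)):
            r_p = corr(B[np.ix_(perm, perm)])
            if alternative == "two-sided":
                count += abs(r_p) >= abs(r_obs)
            else:
                count += r_p >= r_obs
        p = count / math.factorial(n)
        return MantelResult(r=r_obs, r2=r_obs**2, p=p,
                            n_perm=math.factorial(n), n=n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(B[np.ix_(perm, perm)])
        if alternative == "two-sided":
            if abs(r_p) >= abs(r_obs):
                count += 1
        else:
            if r_p >= r_obs:
                count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, r2=r_obs**2, p=p, n_perm=n_perm, n=n)


def write_mantel(res: MantelResult, path) -> None:
    pd.DataFrame(
        [{"r": res.r, "r2": res.r2, "p": res.p, "n": res.n, "n_perm": res.n_perm}]
    ).to_csv(str(path), sep="\t", index=False)
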