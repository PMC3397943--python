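"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route independent of the library
implementation it checks: random-restart optimisation over rotations
for superposition, naive agglomerative clustering, all-pairs distance
loops, exact hypergeometric enumeration for the two-sided Fisher test.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import hypergeom


def brute_force_rmsd(mobile, reference, n_restarts=60, seed=0):
    """Global-minimum RMSD over rigid motions by multi-start optimisation.

    Rotation parametrised as a rotation vector; translation handled by
    centering (optimal for any fixed rotation).  Many random restarts
    of a quasi-Newton search over SO(3) locate the global optimum.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    rng = np.random.default_rng(seed)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return np.mean(np.sum((r.apply(a) - b) ** 2, axis=1))

    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=rng).as_rotvec() for _ in range(n_restarts)
    ]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 2000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def naive_average_linkage(dist, k):
    """Agglomerative average-linkage by direct merging until k clusters.

    Cluster distance = mean of all inter-member pairwise distances.
    Returns the partition as a set of frozensets of member indices.
    """
    dist = np.asarray(dist, float)
    clusters = [frozenset([i]) for i in range(len(dist))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if d < best:
                best, pair = d, (i, j)
        i, j = pair
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
    return set(clusters)


def all_pairs_contacts(structure, probe_coords, cutoff):
    """Residue contact indicators by an explicit double loop over atoms."""
    labels = structure.residue_labels()
    contacted = set()
    polymer = ~structure._hetero_mask()
    for i in np.flatnonzero(polymer):
        lab = f"{structure.res_id[i]}{structure.ins_code[i]}"
        for p in probe_coords:
            if np.linalg.norm(structure.coord[i] - p) < cutoff:
                contacted.add(lab)
                break
    return np.array([1 if l in contacted else 0 for l in labels], dtype=np.uint8)


def fisher_two_sided_enumeration(a, na, b, nb):
    """Two-sided Fisher p by enumerating all tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability
    does not exceed (1 + 1e-7 slack) that of the observed table.
    """
    total = na + nb
    successes = a + b
    support = range(max(0, successes - nb), min(na, successes) + 1)
    p_obs = hypergeom.pmf(a, total, successes, na)
    return float(
        sum(
            p
            for x in support
            if (p := hypergeom.pmf(x, total, successes, na)) <= p_obs * (1 + 1e-7)
        )
    )


def sphere_cap_area(radius, h):
    """Area of a spherical cap of height h on a sphere of given radius."""
    return 2.0 * np.pi * radius * h
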