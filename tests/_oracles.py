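"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the mesh-graph shortest
path uses Dijkstra over triangle edges, and regression quantities come from
plain least squares.
"""

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra


def sphere_mesh_shortest_path(a, b, center, radius, subdivisions: int = 5) -> float:
    """Shortest a->b path length around a sphere via Dijkstra on a fine mesh.

    Graph: icosphere edges plus direct segments from each endpoint to every
    mesh vertex visible from it (segment clearing the sphere). Mesh
    metrication biases the estimate slightly upward.
    """
    a = np.asarray(a, float) - center
    b = np.asarray(b, float) - center
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    V = mesh.vertices
    n = len(V)

    def visible(p):
        # segment p->v stays outside the sphere iff the closest approach of
        # the segment to the origin is >= radius (v itself is on the sphere)
        d = V - p
        t = np.clip(-np.einsum("ij,j->i", d, p) / np.einsum("ij,ij->i", d, d), 0.0, 1.0)
        closest = p + t[:, None] * d
        return np.linalg.norm(closest, axis=1) >= radius - 1e-9

    rows, cols, vals = [], [], []
    e = mesh.edges_unique
    w = np.linalg.norm(V[e[:, 0]] - V[e[:, 1]], axis=1)
    rows.extend(e[:, 0]); cols.extend(e[:, 1]); vals.extend(w)
    for idx, p in ((n, a), (n + 1, b)):
        vis = np.where(visible(p))[0]
        dist = np.linalg.norm(V[vis] - p, axis=1)
        rows.extend([idx] * len(vis)); cols.extend(vis); vals.extend(dist)
    g = coo_matrix((vals, (rows, cols)), shape=(n + 2, n + 2))
    dmat = dijkstra(g, directed=False, indices=[n])
    return float(dmat[0, n + 1])


def ols_multiple_correlation(X, y) -> float:
    """Multiple correlation R of least squares of y on X (with intercept)."""
    from sklearn.linear_model import LinearRegression

    model = LinearRegression().fit(X, y)
    yhat = model.predict(X)
    return float(np.corrcoef(yhat, y)[0, 1])
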