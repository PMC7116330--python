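"""From a small graph to its VB index, step by step.

Builds the 4-node example graph (edges a-b, a-c, a-d, b-c), computes its
degree and Laplacian matrices, solves the standard eigenproblem and
reports the algebraic connectivity and the VB index.
"""

import numpy as np

from vbgrad import degree_matrix, fiedler, laplacian, solve_affinity, toy_graphs, vb_index

graph = toy_graphs()["fig1"]
print("adjacency:\n", graph.weights.astype(int))

degrees = degree_matrix(graph)
print("degrees:", degrees.degrees.astype(int))
# node a touches b, c and d, so its degree is 3

lap = laplacian(graph, "unnormalized")
print("Laplacian:\n", lap.matrix.astype(int))

solution = solve_affinity(graph, "standard")
print("eigenvalues:", np.round(solution.eigenvalues, 6))
# the smallest eigenvalue of a graph Laplacian is always 0; the second
# smallest (here 1.0) is the algebraic connectivity

lam2, vec = fiedler(solution)
print("algebraic connectivity:", round(lam2, 6))
print("Fiedler vector:", np.round(vec, 4))

vb = vb_index(graph, "standard")
print("VB index:", vb)
# 1 / mean(1, 3, 4) = 0.375: the graph is moderately connected, far from
# the uniform ceiling (VB = 1) but with no complete split (VB = 0)
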