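"""Dual SVM on the XOR points — a problem no linear separator solves.

Trains the SMO solver on a precomputed RBF Gram matrix of the four XOR
points and prints the recovered labels and dual solution.
"""

import numpy as np

from mklsvm_pso import KernelParams, gram_matrix, predict, train_svm

X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
y = np.array([-1, -1, 1, 1])
p = KernelParams(m=0.0, d=2, g=0.5)  # pure RBF mix

K = gram_matrix(X, X, p)
model = train_svm(K, y, C=10.0)
print("true labels:     ", y)
print("predicted labels:", predict(model, K))
print(f"dual objective: {model.dual_objective:.6f}  offset b: {model.b:+.2e}")
print(f"support vectors: {model.support_indices.size}/4 "
      f"(all four points shape the XOR boundary)")
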