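# Full conditional distributions of the hierarchical samplers

Model, population i ∈ {1, 2}, marker k = 1..m, region j = 1..J, record n:

    y_i = u_i 1 + W_i a_i + e_i,        e_in ~ N(0, d_in σ²_ei)

Homogeneous SNP-effect hierarchy (one genome-wide channel):

    a_i = r_i s0 + a*_i

Heterogeneous hierarchy (region channels; for marker k in region j):

    a_ik = r_i s0_k + r_ij s1_k + a*_ik

Priors: s0, s1 ~ N(0, I); a*_i ~ N(0, I σ²_{a*i}); r_i flat on ℝ;
r_ij ~ N(0, σ²_ri); every variance flat (uniform) on (0, C] with C a
configurable ceiling (divergence guard).

Write w_n = 1/d_n for the record precisions up to σ²_e, and e_i for the
current residual vector y_i − u_i − W_i a_i (maintained incrementally).
Every conditional below is Gaussian or scaled inverse-chi-square because
the hierarchy is linear-Gaussian throughout.

## Location parameters

**Overall mean u_i.** With ỹ = e_i + u_i (residual with u added back):

    u_i | · ~ N( Σ w_n ỹ_n / Σ w_n ,  σ²_ei / Σ w_n )

**Shared latent entry s0_k.** Both populations see s0_k through their
scalars.  Let x_i = W_i[:,k], c_i = r_i (or r_ij for s1_k), and
ẽ_i = e_i + c_i x_i s0_k:

    precision  τ = 1 + Σ_i c_i² (x_iᵀ D_i⁻¹ x_i) / σ²_ei
    mean       τ⁻¹ Σ_i c_i (x_iᵀ D_i⁻¹ ẽ_i) / σ²_ei

The leading 1 is the N(0, 1) prior precision.  s1_k is identical with
c_i = r_ij of the marker's region.

**Residual SNP effect a*_ik.** Same single-population regression form with
prior precision 1/σ²_{a*i}:

    τ = 1/σ²_{a*i} + (x_iᵀ D_i⁻¹ x_i)/σ²_ei,
    mean = τ⁻¹ (x_iᵀ D_i⁻¹ ẽ_i)/σ²_ei

**Global scalar r_i (flat prior).** Regression of the current residual on
x = W_i s0 with ẽ = e_i + r_i x:

    τ = (xᵀ D_i⁻¹ x)/σ²_ei,   mean = τ⁻¹ (xᵀ D_i⁻¹ ẽ)/σ²_ei

**Region scalar r_ij.** As r_i with x = W_ij s1_j (the region block) and
prior precision 1/σ²_ri added to τ.

## Variances

With a flat prior on (0, C] and k Gaussian terms carrying sum of squares
SS, the conditional density is ∝ (σ²)^(−k/2) exp(−SS/2σ²) on (0, C]:

* k ≥ 3: σ² = SS / χ²_{k−2}, redrawn (or clamped) if above C;
* k < 3 (σ²_ri with very few regions): inverse-CDF sampling on a
  log-spaced grid of the truncated density.

Applications: σ²_{a*i} with (k=m, SS=Σ a*²); σ²_ei with (k=n_i,
SS=Σ w_n e_n²); σ²_ri with (k=J, SS=Σ_j r_ij²).

## Group-rescaling (interweaving) moves

The products r_i s0 and r_ij s1 are invariant under (r → t r, s → s/t),
so the single-site updates mix slowly along that ridge.  Both kernels
therefore add an exact parameter-group move per cycle.  For the s0
channel (flat priors on r_1, r_2), sampling t from

    p(t) ∝ π(T_t θ) |J_{T_t}| dt/t,   T_t: (r_1, r_2, s0) → (t r_1, t r_2, s0/t)

gives t² ~ Σ_k s0_k² / χ²_{m−2}.  For the s1 channel the move also
rescales the Gaussian prior variances, T_t: (r_ij, σ²_ri, s1) →
(t r_ij, t² σ²_ri, s1/t), yielding t² ~ Σ_k s1_k² / χ²_{m−4}.  Both
moves leave the likelihood (and residuals) untouched.

## Derived quantities per draw

    var(a_i)  = r_i² + σ²_{a*i}                      (homogeneous)
    cov(a_1, a_2) = r_1 r_2
    var(a_ij) = r_i² + r_ij² + σ²_{a*i}              (heterogeneous)
    cov(a_1j, a_2j) = r_1 r_2 + r_1j r_2j

Region sums apply the frequency weights 2 p_ik (1 − p_ik) (variance) and
2 √(p_1k q_1k p_2k q_2k) (covariance); see `mtgvar.summaries`.

Deviance (for DIC): −2 log N(y | u + W a, D σ²_e) accumulated per cycle;
the plug-in deviance uses posterior means of u_i, the genetic values
W_i a_i and σ²_ei.
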