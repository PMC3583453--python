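"""In vitro polymerase error frequencies and the exponential length law.

Computes background-corrected per-strand error frequencies, sums the two
complementary strands into allele-level MS error rates, and fits the
log-linear (exponential) dependence on allele length.
"""

import numpy as np

from maturems import MutantSpectrum, PolReaction, fit_exponential, pol_ef

# per-strand reactions for a series of allele lengths (observed and ssDNA
# background mutant frequencies; spectra pooled from two reactions/strand)
rng = np.random.default_rng(2)
allele_points = []
for units in (10, 13, 16, 19):
    reactions = []
    for strand, scale in (("GT", 0.4), ("CA", 0.6)):
        ms_ef = scale * 1.5e-4 * np.exp(0.30 * units)
        spectrum = MutantSpectrum.from_counts(n_expansions=6, n_deletions=14, n_non_ms=5)
        # observed MF implies the planted MS EF after background subtraction
        # and spectrum scaling (20 MS of 25 sequenced)
        observed = ms_ef / (20 / 25) + 1.0e-3
        reactions.append(PolReaction(strand, observed, 1.0e-3, spectrum, units))
    result = pol_ef(reactions)
    allele_points.append((units, result.allele_ms_ef))
    print(f"(GT/CA){units}: strand MS EFs "
          f"{result.strand_ms_ef['GT']:.2e} + {result.strand_ms_ef['CA']:.2e} "
          f"-> allele {result.allele_ms_ef:.2e}")

fit = fit_exponential(allele_points)
print(f"exponential fit: EF(n) = {fit.a:.2e} * exp({fit.b:.3f} n), "
      f"R^2 = {fit.r_squared:.3f} (log scale)")
print("the per-unit log slope b means each added repeat unit multiplies the "
      f"polymerase MS error rate by exp(b) = {np.exp(fit.b):.2f}")
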