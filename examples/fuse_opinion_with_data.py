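"""Statistically combine opinion-based and data-based bias distributions.

The pooled opinion is treated as one observation of the bias and the
empirical distribution as its prior; the conjugate posterior is a normal
whose precision is the sum of the two precisions.  The combination is
symmetric, so it does not matter which source is called the prior.
"""

from biasmeta import BiasDistribution, combine_normals

data = BiasDistribution(mean=-0.16, sd=0.09, source="data", profile_key="XXL")
opinion = BiasDistribution(mean=-0.10, sd=0.16, source="opinion")

fused = combine_normals(opinion, data)
swapped = combine_normals(data, opinion)

print(f"data-based:    N({data.mean:+.3f}, {data.sd:.3f}^2)")
print(f"opinion-based: N({opinion.mean:+.3f}, {opinion.sd:.3f}^2)")
print(f"fused:         N({fused.mean:+.3f}, {fused.sd:.3f}^2)")
print(f"swapped roles: N({swapped.mean:+.3f}, {swapped.sd:.3f}^2)")
print(
    "\nThe fused mean lies between the two inputs, nearer the more precise "
    "data-based source, and the fused sd is smaller than either input "
    "because the precisions add."
)
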