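pwb5_score,t_score,provenance
0,19.0,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
1,21.1,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
2,23.2,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
3,25.3,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
4,27.4,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
5,29.5,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
6,31.6,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
7,33.7,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
8,35.8,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
9,37.9,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
10,40.0,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
11,42.1,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
12,44.2,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
13,46.3,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
14,48.4,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
15,50.5,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
16,52.6,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
17,54.7,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
18,56.8,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
19,58.9,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
20,61.0,synthetic placeholder (non-canonical affine map; replace with the published linkage table)
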