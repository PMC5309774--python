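# Curated residue selections, markers, base-pair lists and interaction
# catalogs for the L1-stalk analysis.  All residue numbers use E. coli
# 23S (or yeast 28S) author numbering; entries are chain-agnostic and are
# bound to a chain id at load time (per-structure chain maps / numbering
# offsets belong in the dataset manifest).
version: 1

selections:
  # conformationally static large-subunit rRNA core (bacterial 23S)
  bacterial_23s_core:
    - [173, 269]
    - [292, 344]
    - [372, 542]
    - [552, 626]
    - [657, 926]
    - [938, 1053]
    - [1108, 1373]
    - [1375, 1412]
    - [1425, 1478]
    - [1552, 1579]
    - [1587, 1718]
    - [1744, 1859]
    - [1882, 1906]
    - [1930, 2088]
    - [2227, 2787]
  # conformationally static core (yeast / Plasmodium 28S)
  eukaryotic_28s_core:
    - [16, 114]
    - [180, 234]
    - [270, 433]
    - [626, 704]
    - [788, 1062]
    - [1109, 1228]
    - [1282, 1554]
    - [1583, 1622]
    - [1653, 1705]
    - [1780, 1807]
    - [1819, 1948]
    - [2101, 2219]
    - [2225, 2249]
    - [2273, 2430]
    - [2596, 3150]
  # mobile domain: helix H76 strands
  h76_mobile:
    - [2093, 2109]
    - [2181, 2196]
  # static domain: helix H75 strands
  h75_static:
    - [2083, 2090]
    - [2229, 2236]
  # helix H68 (minor-groove interaction hub near the 50S E site)
  h68:
    - [1846, 1894]

markers:
  # phosphate at the top of the L1 stalk head domain
  bacterial_stalk_head: {residue: 2127, atom: P}
  yeast_stalk_head: {residue: 2469, atom: P}

groove:
  # major-groove width at the proximal end of H76 (opens ~11 -> ~20 A
  # between the open and closed stalk states)
  h76_proximal: {a: {residue: 2093, atom: P}, b: {residue: 2189, atom: P}}

base_pairs:
  # approximate Watson-Crick pairing of the H75 and H76 strands,
  # 5' strand listed first; users may override with a curated list
  h75:
    - [2083, 2236]
    - [2084, 2235]
    - [2085, 2234]
    - [2086, 2233]
    - [2087, 2232]
    - [2088, 2231]
    - [2089, 2230]
    - [2090, 2229]
  h76:
    - [2093, 2196]
    - [2094, 2195]
    - [2095, 2194]
    - [2096, 2193]
    - [2097, 2192]
    - [2098, 2191]
    - [2099, 2190]
    - [2100, 2189]
    - [2101, 2188]
    - [2102, 2187]
    - [2103, 2186]
    - [2104, 2185]
    - [2105, 2184]
    - [2106, 2183]
    - [2107, 2182]
    - [2108, 2181]

catalogs:
  # transient bridge between the closed L1 stalk head and the 30S subunit
  b9:
    - name: G2141-S11
      a: {role: 23S, residues: [2141]}
      b: {role: S11}
    - name: G2116-S7
      a: {role: 23S, residues: [2116]}
      b: {role: S7}
    - name: G2148-S7
      a: {role: 23S, residues: [2148]}
      b: {role: S7}
    - name: L1-S13
      a: {role: L1}
      b: {role: S13}
  # helix H68 network: B7a bridge, static H75 A-minor patch, tRNA
  # acceptor arm, and the H76 G-U-region minor-groove interface
  b7a_h68:
    - name: H68-h23-B7a
      a: {role: 23S, residues: [[1846, 1848]]}
      b: {role: 16S, residues: [[698, 706]]}
    - name: H68-H75-A-minor
      a: {role: 23S, residues: [1853, 1854, 1889, 1890]}
      b: {role: 23S, residues: [[2083, 2090], [2229, 2236]]}
    - name: H68-tRNA-acceptor
      a: {role: 23S, residues: [[1850, 1852], [1891, 1893]]}
      b: {role: tRNA, residues: [[1, 4], [70, 72]]}
    - name: H68-H76-GU-region
      a: {role: 23S, residues: [1856, [1886, 1888]]}
      b: {role: 23S, residues: [[2097, 2102], [2187, 2192]]}

classification:
  # stalk-state boundaries (degrees): midpoints between the group means
  # open 4.0 / intermediate2 14.4 / intermediate1 20.4 / closed 26.5
  boundaries: [9.2, 17.4, 23.5]

contact_cutoff: 4.0

backbone_atoms: [P, OP1, OP2, "O5'", "C5'", "C4'", "C3'", "O3'"]
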