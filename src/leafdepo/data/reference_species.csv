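species_id,binomial,family,life_form,leaf_texture,cluster
LiLu,Ligustrum lucidum,Oleaceae,tree,Leathery,3
CeDe,Cedrus deodara,Pinaceae,tree,Leathery,3
PiTa,Pinus tabuliformis,Pinaceae,tree,Leathery,1
PiBu,Pinus bungeana,Pinaceae,tree,Leathery,1
ViOd,Viburnum odoratissimum,Caprifoliaceae,shrub,Leathery,3
PiTo,Pittosporum tobira,Pittosporaceae,shrub,Leathery,3
BuSi,Buxus sinica,Buxaceae,shrub,Leathery,1
PhSe,Photinia serrulata,Rosaceae,shrub,Leathery,3
InTe,Indocalamus tessellatus,Gramineae,herb,Papery,1
PhVi,Phyllostachys viridis,Gramineae,herb,Papery,1
TrFo,Trachycarpus fortunei,Palmae,tree-dwelling,Leathery,2
MaGr,Magnolia grandiflora,Magnoliaceae,tree,Leathery,3
ErJa,Eriobotrya japonica,Rosaceae,tree,Leathery,2
OsFr,Osmanthus fragrans,Oleaceae,tree,Leathery,2
PlOr,Platycladus orientalis,Cupressaceae,tree,Leathery,2
TrRe,Trifolium repens,Leguminosae,herb,Papery,1
JaMe,Jasminum mesnyi,Oleaceae,shrub,Leathery,2
IlCo,Ilex cornuta,Aquifoliaceae,shrub,Leathery,2
FaJa,Fatsia japonica,Araliaceae,shrub,Leathery,2
NaDo,Nandina domestica,Berberidaceae,shrub,Leathery,2
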