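scope,diagnosis
ichthyoses,Ichthyosis vulgaris with follicular keratosis
ichthyoses,Autosomal recessive congenital ichthyosis
ichthyoses,Sjoegren-Larsson syndrome
ichthyoses,Ichthyosis follicularis with alopecia and photophobia
ichthyoses,Hystrix-like ichthyosis with deafness (HID) and keratitis ichthyosis deafness (KID) syndromes
ichthyoses,Other ichthyoses
other_cornification_disorders,Pachyonychia congenita
other_cornification_disorders,Morbus Darier
other_cornification_disorders,Warty dyskeratoma
other_cornification_disorders,Keratosis lichenoides chronica
other_cornification_disorders,Keratosis pilaris atrophicans
other_cornification_disorders,Bazex-Dupre syndrome
other_cornification_disorders,Congenital alopecias
other_cornification_disorders,Hereditary mucoepithelial dysplasia
other_cornification_disorders,Porokeratosis
other_cornification_disorders,Porokeratotic adnexal ostial nevus (PAON)
other_cornification_disorders,Naevus comedonicus
other_cornification_disorders,Familial dyskeratotic comedones
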