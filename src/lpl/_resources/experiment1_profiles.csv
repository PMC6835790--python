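segment,product_id,measure,value
women,wine1,overall_liking,3
women,wine2,overall_liking,7
women,wine3,overall_liking,8
women,wine4,overall_liking,7
women,wine5,overall_liking,9
women,wine1,sweetness,-2
women,wine2,sweetness,1
women,wine3,sweetness,0
women,wine4,sweetness,-1
women,wine5,sweetness,1
women,wine1,acidity,-1
women,wine2,acidity,1
women,wine3,acidity,0
women,wine4,acidity,1
women,wine5,acidity,0
women,wine1,astringency,2
women,wine2,astringency,0
women,wine3,astringency,1
women,wine4,astringency,-1
women,wine5,astringency,0
women,wine1,body,1
women,wine2,body,0
women,wine3,body,2
women,wine4,body,-2
women,wine5,body,1
women,wine1,fruitiness,-1
women,wine2,fruitiness,1
women,wine3,fruitiness,-1
women,wine4,fruitiness,0
women,wine5,fruitiness,1
men,wine1,overall_liking,8
men,wine2,overall_liking,4
men,wine3,overall_liking,6
men,wine4,overall_liking,9
men,wine5,overall_liking,6
men,wine1,sweetness,0
men,wine2,sweetness,2
men,wine3,sweetness,2
men,wine4,sweetness,0
men,wine5,sweetness,1
men,wine1,acidity,0
men,wine2,acidity,0
men,wine3,acidity,0
men,wine4,acidity,1
men,wine5,acidity,-1
men,wine1,astringency,1
men,wine2,astringency,-1
men,wine3,astringency,-1
men,wine4,astringency,-2
men,wine5,astringency,-1
men,wine1,body,0
men,wine2,body,-1
men,wine3,body,-1
men,wine4,body,-2
men,wine5,body,0
men,wine1,fruitiness,0
men,wine2,fruitiness,2
men,wine3,fruitiness,2
men,wine4,fruitiness,-1
men,wine5,fruitiness,0
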