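analysis,statistic,expected,kind
1,n_trees,201,count
1,best_length,117,length
1,ci,0.60,index
1,ri,0.77,index
1,strict_length,135,length
1,strict_ci,0.52,index
1,strict_ri,0.68,index
1,majority_length,120,length
1,majority_ci,0.59,index
1,majority_ri,0.75,index
2,n_trees,7,count
2,best_length,116,length
2,ci,0.61,index
2,ri,0.77,index
2,strict_length,120,length
2,strict_ci,0.59,index
2,strict_ri,0.75,index
2,majority_length,117,length
2,majority_ci,0.60,index
2,majority_ri,0.76,index
3,n_trees,8,count
3,best_length,106,length
3,ci,0.63,index
3,ri,0.78,index
3,strict_length,111,length
3,strict_ci,0.60,index
3,strict_ri,0.76,index
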